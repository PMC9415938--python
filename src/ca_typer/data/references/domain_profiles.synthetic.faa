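>GAF_CcaS kind=GAF synthetic exemplar
LDILPSFPSWDDLVVQPSENEDGQPATVSNSGIILRKVAKEKKKCTPKSAVFQLMASRNGNLTSAQEDEIVDERRRCLSPGNICLVLESSKCAVGIFCPQGSFSTEKRSMHDVAHREHAGFFIQNLMVLHAYFSNGRGKLAAALPHIPEFNSRRLK
>GAF_RcaE kind=GAF synthetic exemplar
ESNTKWACLDVLPNYPGWFFLVIQVGENERSQQCSVHNHGITGRQLAKEKKIDQKKSAYFQLVASGNYPLNKYQDNTSVDDRIRCLSPGEFCLIQEESPVAVGPWAPQGSFSVKEASLPSVSHLESEAFEVQLLLVLHAFNTNARGMLAKELSHIREAKEQRLKV
>GAF_RfpA kind=GAF synthetic exemplar
GFHIDHGTKWANLGVLEAFNGWWDVVNQPVNNEEHQQFEVSNSGIVLRAVNKQKKLCAKKTAIFQMVASKDDALNPMQEDESINDKIRCHSLGHFCIVLEESQVHVGIKATRGPWSTKLASLPDVSHLETCGFVVQMFLVLKAYNTNLSFKLAQKLAHHPRIAHHRAKID
>PAS kind=PAS synthetic exemplar
ASKLADSSVNVLDIDCVKVALNVYIMVVVGTSVKDPSFQGAAAGPRGATAIILRKVYRIKDKELVAEDEEKILVAEPLRLMGCKLVAPRVAAGEYTSVLSAELCEQTGSP
>HisKinase kind=HisKinase synthetic exemplar
NWVKSRGDGKILLLAMQITRMDFIAGSQSDGPLLPAKTGEYRCTQNNVVNTPASTHGTEVVQQRLEDLRCIMNVECIPDKNTQWFAQEDEASQTLITNVQTLYGVPPLRFHRDFENGFSDNWDTVGAANPNETIISDEMHTFNQTVPHNTPMTKLDGLVHCGRYINWRILLMFDPIRPIYYINGHQRGLPMDPKPPKIMGHLRMQRPVKIEFYRINQYTS
>PBS_linker kind=PBS-linker synthetic exemplar
TPGEQKNNCLLALNIRTAAELIDAVCLHILNGKMHSPIMAKEKELLDKSGYIGNHLSPFVQDTDAEQDIELYMGDDEPLETSKKTRTEYDVLEPACGDLAILEEFYQQLRTVLCVIAAAVDFIKAFGPTAPLIYDIFELRPLSLASQVGFDVFNKAYTELKQSVLLACVEKLERLLVKDLLSHVTHDPAD
>phycobiliprotein kind=phycobiliprotein synthetic exemplar
FNLVRGPPSFLTHLFFNSKDTQGIYVMQRGLQGIEVPRVFHETLPARGFNSEWEAKRECRIHAGYYANPSGHYPEMNNDSPTNPALAGPHSGDRMRFGGLQANAVSVNIRGKRVAGARKFTRGPTEYSALYAMMPIGDLMEHHARLAGAVELACSTPSKIVP
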