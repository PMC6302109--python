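>PolA_anchor synthetic stand-in for the E. coli IAI39 PolA reference
MWQIDSINPGIWSVDICYQFTTHQDLNASVRNYIKILQLHPMCIHCAGFTVTLQQLKYLT
IFVNNYCSFITLEMSWCRSIFLECGLPFGCLCHFAQAEINYPHYRLKSAAAPKYPAWWGE
DQCAHCFDVWESCQWPFGWMCLMYVLGRWIDWFVWYSFHVHLQMTMPCPVKPGDKRHDGI
LQDLSCWPMILIQEREWYEPTNPSCIAEMPVKTKCCVKFCFWDIGRINCKMHQACQPCNF
LYEISITQMGSIWHCQICTIWYVPFLTGRARWCWCYLLCNFGCTDNNGCGGILQWSTDSW
RSETNEVDGRFWCHSCIHQTETQFLEFLQHRVDLAFIKGFDRRYGPCFKTYIVCGENIFT
VFGSPCLTWRECVAFGLEWPHLENVGMYLDHQAMKYSYCLQKKIAEYQDVSLGWRFFGFY
KWFMVNDIYAGIFYQMETDEKRTNLYFHVLSGLRRCWRHTGFGIAHSVSEKWVCDAYTRC
ANEMCVQQSYSQFHIWQCQQWDCEQINLSCVKRMYGSKYSMEDHWGYFDAIYQMDHCVFA
HDSARAWARPFRGIIWYSCYHSVMVCIDQHSDMPTCEMAIAISCGRQSWHEIVQADHPHH
PRTPLHVGEINGKSPSFLSFALISLMLAFCFICTIKLPLNTCYLDKFLMWDGIYALGLVR
TLHCTNGCLWMHEWGMHSDMGFGYMPTLPWFNMKEEPHPTGEVLNPQKMIFAVTACWKWC
KHISKWVAYHEQKIPYCDLDSRPQVWHCAAQDGWSKQKRGQFHDISRARRTMAEWFAART
HNWRSMPCCRIVVGHIAYHPSDHEEGLWVTDAYNSFFFWMHEIQPAPAEGWCEVESTNER
PAKFQMDTMNSHWGQVNNTVIDKTNCYISKECRWIKRCGQEHRNAQGYMNVPPYEHHHHR
DPVHYWWYKYMQVTCWLNLWTNKHIMKE
>NrdA_anchor synthetic stand-in for the E. coli NrdA reference
MEMNFTGGCQPLHVTNPYCFEDKHTSYMLWQYNWDENNYRGWQDHPTCHRPNLDTDHMGL
IMYYGYRGWCGGLTNGYDTPPQYEVCSEFFSITNYWNHEPQQVGSNQYVYLKPTYHNTVI
DSICIFVPCFCGYQAGFHITLDWACTYWKQDPFVMMHDYIQKFVQPCCNQWTSCTWICTQ
GIMMFEIEKGQSATHSGHIHKKQEKIGMYGIEACALFMSHHAELHYTNFLFLDHANSEHV
KLVQACVIMETEKPNQMPTHGVWSYNGIARSGSFVARRIEEHSLQLGTKDAPTMMFSHLI
TDDCCEKKQVGGQTHVVFFTILFMKSSLFPRDMCVTNMICPSCSIGSRSYPNAVNDNCPI
GDVYLEELKCAAFSIQIIVTVRQMVSMPKCMGAMSHGNFQCHYNCGAQVAPYLMKIEKAE
WWCLDLTDLLMGYKYRVRWFPLPVKNWGHEMEIHTEDSLYWYIRPMLTKKDAHYADFCQS
GMTPRPVKPCVMPYEMIVQVIQLFEWYTPSNCKVGPWPECNSTSPGDDEQKEDKYRWLIS
MERVWNDMFDRNIIFWCDCMKLCWKVHLHVWNTDPCLKRWGSPWVYTRPINGMSTTNYYP
RVAGIGWLWEEVQTEWEEMQAARDVMRRFQWDTHELYAPNDLLNNYNLWYVNFLDESTCH
FGSITMHILSPFRFLPNARIVTCWFQSECIMKMVWFFREKTRTQRVNQFGMKWKMEMWPF
HHGYKQETQAPQQKHYGVIPQWAREDPNFWGDWPTCWKSRA
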