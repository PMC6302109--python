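>PolA_exemplar|PolA synthetic exemplar
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
>Gp4_exemplar|Gp4-like synthetic exemplar
MYDMVLSNVQTMNEPMWVPYFMINYERAVSHGFCTFWFCKITQCGEVMVHYNQWASGMHA
HPQAAFQNRLSIMRSFSMLETLFRKIWPWSCLAARGCPMFNNWFLIRAHYQAGWRFVIIF
WMIYSIRAQIVGCIKFPADLQSKKRDRYKCWSATFPHCRVSLWGQIPCSRWSCVYQGDAN
THYNTPMFGGTFEIKHIWPCTHDITKYFRIELCYWCYFWGWSFAHEQKWWWPLEHMPLTC
NDFNSQRGGCMWKGYCWRIIATYNEWAYEQHKISNNWAWYLVSYSQPMFCSCYITLWAQI
MAWILFSSCNDQWNKMWKCMQFPQAGVCIVAMHTITYTRCWYTVWEIEIMIQCHVKKHGK
GQEKHAILCYKFNDYVFEDHALNDYEHPQMDYKSWRHIER
>DnaB_exemplar|DnaB-like synthetic exemplar
MHKKGTFQDHHKGNKTWFWWVHGSQMWHKNLLQEDKLWAQYDLRFQLLRARNLGEMTIDK
EWEWAELFEYHNVQWNMDLNVAWACAEMMCRAYCMMFPFFAWKESKRPHPCFKENGLNWT
SEFLEFESEICECQYMAQEFHGDHETFGGQGPHQIKMSFLGGGLMQMDMRRMHWKMIVRE
HDVLKAPLFDFTWSQLQDRTRYDMCHIKTSPEDEAFSVNRTWVWANRGFPTVNTQAFYLK
MFKGMWFHIKTDSLIPNLCHYNSIPIMHHLNLMYPEKTVSATSWQFYYGIYYWGWGHLWN
LCYFLQFQMNCNVRFWTFPMILHVQIFTRWFQFVYSCSLEDDDFNLFKQDDNGNIDWEQT
LFSQNSQFKCRVCTWETYATVREHPHHHVFYNKTYLTHKSQLIGTWLWVMNKEESPYNTA
VYACDGKMYCTWVRGQAQYW
>UvrD_exemplar|UvrD-like synthetic exemplar
MSWHYCKFPHAVTPVKDRTVWELDHRRTIFCYGLHAERIQHRHEFRIRGGTKYFSYQANL
LTDWWMYNHQIITFPRDGHYLYQCWRAPVVMWFWFSYQKMAPRAIGVKVVDGKKTWAAER
YTPCLGICRLNACMCWFHFFKWMGYWNCGENIPKTIRIASGAPYQHPPLMFKHPEWYDVC
FHCDKHMAVKGHGQCMVCDCEIDCEFIYWTFSGRPVCAYNWGETDIRWWARRVSGFQFAV
TCHWCVRIHFKEELPVCMWSAPIHGNMRHNGTVSNQTNRSEACCHKYEPDHQWHTPMHNQ
CWPIYYVNRKTLSFTNWCMRVEIDSHYKGFTAKDDGYDDLMFMEIMAEPFTAAQEAHHVK
KDIAHKHEMWYKTQVFARSHQFAWHVTPICNWSTHWKWMFEGWWMCVYNILTRGVCGMQS
VNAHCGPIGAAPFANTLPGNAVMRHEPGKHLHHSTLLMQC
>RecB_exemplar|RecB-like synthetic exemplar
MMVTFPPFLAMFICKGSYPSVKKCSDAFYFTFRMEEKMIEWLENQQLRVKITFKWQCLMR
MGVYYMKKVYEPEPPNNWTDQENPCSDPHHIWVRKRYKLNFGPTPFHESIANQPIKLETI
RTVATVFWEIPILAGFPPHCCYTTTQMKHWYPKYQNMYMHGDGKIHHIRQEKATNCTMMN
IFLIWDVIRRFQYRQRVFVQIFGVHDELYQFSKADMVEMDNMDWVAPWYTDTLFAFTVCI
HVVDHKCVLAVIWDSCTFWTYNLHWLDAPTPYVRIIIYHMLIAFISMGCTIYDMQDFPRC
LIYETYRFGSPPPECIEEFYAHWFMQVVVHEQCEPAASGGYFHVRGMYLGENTSYWEYSL
HANQQHGHQNKHYSKERMQLQWWSSTGCHECFECKEVETTECPIVTIVAYLRNHHSFWGG
THKHRSERKAEWERMFQSSPRNMAIYKPCPQIHRWMWTHMTNFCVSNVLDHPYEPTFMPH
IIRALLVADYTEMHGQFLEP
>SNF2_exemplar|SNF2-like synthetic exemplar
MWMFKTVECKHDGLNCFIQYDVMPDLKVWVCWVKSFKPMVKELILLQHVSHYDLRWIIHA
CHGAFRVWWRLQDKTPYCGLGYACLCFVHHTAHPWYKHQMWYDMQDNIIHTPRSQFPYPT
KHMAITVFHVAMTGPWCFHYVHHNWANICMLPVTFLRLMYHQGQFGEPYTNMNFSCTCPS
MENQVFQQMGRAQAGDIARRQEWQFSTDRDCSGMRCDGLGPNIVAIIHTCHCTQHEIEYH
PQNCACDMYSRNVWWVNFTDYMSMQHRCFDEQFTLVNDVSHHRHWSIYDSANPIICVGHW
RDPFVHLIFCMANECCVGESHIGEWGPYGLVGNCTIKLPGVPHRNERNEDCMHLHESCLL
VYSASRRFGFACYIEHINTVLNQWRGITYMPVHCEHYHIIHYCDQPPEPEPGSMKFNHPG
MAYWALPVMIHRHWQTACNIICEERRLVTKPPAQTYVDKYDRMDMEQMETIGMHWHTRSI
>RecA_exemplar|RecA-like synthetic exemplar
MVQIEYAHTVQDETCVYPTVHSQYIVSCKTMPKTINMKAEMNSPDGIGGKSRVWTKIQRL
GQEVKHWDWLAFKGPQKVTFHEPRQMKGSWCMSSINQSWTRANNLMVSRMRNIPCYDGKY
YYIHIFMYSYWEASQKECHEIHQDARPALLFSSAMINWMREQEFFTAYLCVSVQQGSQNW
MHPEPHQFQGNNDGTTSILFVVWKAFFCVREIHIQDIMRANGWIEGDLAVLMREWMGGYK
IPKEFGEGRYIWSISHPCVHYFLHMASQPYMYLKHTPIAERCAYTFNLLWALTMYKTYSR
QNQESWDDPWPGHGTYTLDHCVHSRMERHRPSYNFQWLGD
>DnaG_exemplar|DnaG synthetic exemplar
MGGLSVTNQTILNTIGCQEYRLYNHPVMMCCHLAMRMDIMTHICSLTLWMFLAWFDWEDA
PPMDLTVRVVPWAQKHTKEQVCDGDFGWWHEHPYASRSMFCCMHYNAFANPGDPVRPYDF
PISFTTEYCWVEWIHHGSINQVGSKKQTLSRTYKGEFSVKTVLMVTRWLKMYVQIHWNRF
YMQCGYDLETMGVYIFHMKKITGCMEVFTCFPPLFWVWVGVCFYYAFSLYILYIRMRIHF
NFQTQWYKQCCDHMMPPFQTAILDNPIWKWEGGLPRMNQKEKSWTHHMDMSEDETNGNHW
HHDWDTILIKNFNYEYLPVQTAMIRSETKQFLETDPGVCNVCFCEMNRQATFNPRMPVWI
PRAYSDGIGHNKVTLPCDNH
>MazG_exemplar|MazG synthetic exemplar
MYTQWFAMTWVSQTNWWGSDENWWMAWFRWPRYSFFYCNPSADWCPHYHVHVARTCWPSP
MYWQLVCYYQCPEECPWEEFARDWHRSRNNCDWWLGCPQVGNPWWYYTGANMCSQNWFVV
LGLACCFGVYTDECRCPYFVSHMIHTEHMLSIWYDGLISYEFAKFCSTCMMNTWLAIFAY
GKYMVHHYPTNMMNYVHQTK
>RNR-I-Other_exemplar|RNR-I-Other synthetic exemplar
MECNFTGGGQPVHVTPPFCDCDMTTSYYLWQYNWDSNIVCGWQDHPTCHRDNLDADHMGL
IDCYGYRGWCGGLTNVWSTPPLYYHCSEFFSITNPWNNEPGQWGSNQDDYWRPTWHNTVI
DSICIWVNSFDGIQAGFHCTDAWVCTYLKVDQFVMIHDYIQKFVTISCTSWTSCEWICVQ
GIMMFEIEYEQSCTASGHKHEKLEKGGMYGIEACRVFMSHHLENHPTQFLTLDHSDSGHV
KVVQTEIRMETEHPNQSPTHGEWSYNGLLRSGSFVARRIEEHGLQLTTKNACTMEFSQLI
TNGCCPKKQVGPWTEVVFFTILPSKSRLFPSDMCVTHMICPSCSITPRGYPNAYEDYCPM
GDHYLEPLKGTEFSIVIIVWVGIMVSMPKCMQAMSYGNFVCHQNCGAQWCAYFGKDEKAE
QWSLDPKHLRMGYPYRTFWFPLPRKNWVHEMEIHTEISLYWYIRDMLIKKDSHYAHFCHS
RFTPLPVKPYWCTYGMYVQVIYLFEEYTPSNCKVSPWEEIYSTGPGYDEVKEDKYQWLIY
MESTDNYMFDRQIRTWYDCMHLCWKVHRLVWNTDPCLKVQGHPWVTTRPCNPMSTKCCYC
RVAGIGDLMEEIDTEHEEVQAANVPMRNFQFHWDFLMAPNDLLNNPNLRTVNDLDESTCH
FGMIFMHALSIVRFLPNARIVTPWFQSECIMKMVWFMREKHRIRRWNQCGMSWKMAMWPI
HHMYWWTTTAPQQKHPGKIFQWAREVPNFWKDFPTCWKSRA
>RNR-I-CyanoSP_exemplar|RNR-I-CyanoSP synthetic exemplar
MEMNDTGGCQPIHVNNPYRFEVKHTSTMLWQYNWDENNYRGWQDIPTCHRPLLDTDAMRL
IMKYGYRGWCEGLTNFEDTSPQYEVRSIYFDITNLWRHEPQQVGHSFPNYLCQTYHNTVI
DSISPFPPCWRMYQHVFHIVLDWACTEWMQDHFVMQKNYSQKVVQPKCNQHLSGMWIMPQ
GISMFEIEKGQSATHSGHAHKKQEKIGMLGIAACGLFMSHHVNLGYTNFFFLNHASSKIV
TLVQASVIMLVCGPYQQPTIGVTSYWGIARSGSFVARRGEEHSLQDHTIDLPTMMFLHLD
YHLCVWKKQVHGQTWGVFFTIIQMKSSLFPRDNCYTEMICPSCNENSREYPNAWNDNANI
GDAYLEETKCAAFFIHIIVPVRQLVSWPECMGYMGHGTRQCHPQKPWQVAPYLMKHEKAA
WKCLDLIGLLMGYFGRVRWFPLPVKQWGHEMENHFEDSLYCYIHPMLTKKIWHRHDFCQS
GVTPRAVCPCVYPYEQIVRVIQLLECYTPEQRKVHPWPECIKTSPMDDLTMSDKVRDLFP
MEWTPNDCFHQNIIRWKNCMSLCGPHHRHVYNTDPCLKRWGAPWCYTFPINGMSTLNYYP
RPAGIGDLWCAGDNEGEEMLMARDVMRRFQWDWHELYAFSDVKNHNKLPYVNFLDASTCH
ILAIPMWCLSPFRFLTNARGVRCTFTSECQDKEVWFSRESTMTQRVNQFGMKWYMEMWPT
HHGYKSETTACFQKYECVMPQWAREDPNQWGYWPTCPKSRA
>RNR-II-Other_exemplar|RNR-II-Other synthetic exemplar
MEMNFNVGSQPQGVDCPPVSEDKNTSYMLNMHNWDENNYRCDQDHPTNHRPNLDTDHMGH
IMYYGYTGLCGGLTNGYMTPPQIEVCSEFCKIGNYRNHEPQYVGFNQYVYTKPTYNNTTI
RSVCIFVTCACFYQAGNAIDLNWQCTYWQGDEESMEHDVMQRFVQPCIQQWTSCGCICTK
GIMMFFIEKGQGLTHSGPIHKKIEKIMMGKIYACALFMSHNANLKYTNFMFLDFANSEHK
KVVQAMCIMEKYKPNQMYTTGVESYNGISASGSFVARRINSHSLQVGTKCMITMHFSHLI
TDACQSMKCVGGCTHVVFFTILFYKSSLFPRDMCVTEMVCPSCSAALMSYPKRPKDNPAC
GLVYSEELECGIFPIQIIVTLRNMVSMQKCMGAMSHGNFFCHKWCGNLVAPCLMKTEKAE
WWCRDLTDLLMHYKAKGREKYPPHKNWGHEMEIHIHDSLYTYINPMLECKDAMYADWCQK
GMTPWEWMPCVKPYEMINQVISTFAWWTTSNMKVFPWPECNSHSAPDDEMKNDKHRWLPS
GETGWNMMFPRNIIFNWDCMELCWKVWDHVLNTDFEFGRAGSLVFYTRPIPGMSTTNYTP
WVAGILMLWEWVQLEGEELQANRDVMCRFQWDRHEDSASHDLLNKYNLWYVNFLDESYCH
FGSITMHILSPFRFLPNAIFVTCWFESEQIMYMVWWFREKRRTSRVKQTGMKWQMEMDPF
HKGLKQETQMPSQDSYGVIKQWVRADQPFAGYWSTCVGVRA
>RNR-II-RTPR_exemplar|RNR-II-RTPR synthetic exemplar
MEMNNCGSCSPLHDWTQYCFEATASRYMLWQLNWPERNYRGWQDHITQSRMFLDTDYIGL
IMAYQHRENCGCAYNGGDNPPQKFSTAEFFSITMYMNHEPQQVGSNQSVYLKPNYKNTVI
DSGCIFVPCNCGYAAGFYDTLDWACGYWKKDPDLMMHDRIQKSVQPQCNQWQMCMWECTQ
HKPSFEIHKGQSITHGRLIHKYQEKKGSHIIEERALFPSHMAERHYIHVWFSDHANSECV
KEVQACVIMETENPLLMPTHWVWAYNGEARSGSFVARTIEEHWYNLYTKDTWTMMGSHLI
GRDCCEKKQRRKQTHVVFFKILFMKSCLFRFDMCVTNMAHCSCSIPYRSYRSAVMDNCPI
VDVWMREDKCAAKSIQIAVTVRQMDFVKKCMGVMSHGMAQPIYNKSAQFVPFLMKIETAE
WMFLDLTDALMFYKYNVRWFPTPVKNFGHEMEIYTEVLLYWLIRPMLTKVDPHYADGCQS
GMQPGPVKPCVECYEMIVQVINLFEWYTPSSCRHGPWPECNWTSSGDDYSKEDKYRLLIS
YERVWNEMFDRNIINWVDCMCACWKHHNQVWNTDPCLIAWGSCWVYTRPINGSSTTNYYP
RVAGIGWIWVLVMTEWEEMQFARDWMFRFQWRIHELGAENDLLTWYNLWYVNHLYESTCE
EGYITMFILSIFRFPPNPWLVNIWFISECRMKMVWFFVDKVRTQRTEQFGMKGNMYMWEF
HHGYKFTKQAPQQYHYGNHPQLAREDAGFWCDQPRCWKSRE
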