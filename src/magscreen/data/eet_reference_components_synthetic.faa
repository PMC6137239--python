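>gpcc_porin_ombB synthetic stand-in reference component
QYAVSMSYDIRKGRKFNGLNPKNVNDIPPGIKYVLKLVKSFLDWYYADVMLLSDNTQKPQPLTNRMLPSF
MSTNQWTSWTDIERLWFYTGYSVPWVWLVIIYVYQLYFTSLDFYALKLTRMDDTKTGTMDDDLMKDQKQA
RIRPRKPWGDNIFRQETWPMWRFKLKVLPILAIANSKTAPWTMAYAPERGPNDPIIFVEDWGMTPGNFIK
GNMTWPNDEIIAEWETGNWYVQYQFKQIDLYDEMLFLTTDVQAPRKQTSPALLLKWVAYVKSQKQRRYKF
SPEMQGGLVEPTTQSSPTLVSREKENAADFNGTDVWAYMN
>gpcc_periplasmic_omaB synthetic stand-in reference component
FPESMCMKCHQMKEEVDMNNRVRSMRPLQFVDIKVDPNTDAGCFQCHVNMGRELIRSFEKMGGKNDFKFK
ASNADAEFVYCNFCHEFMLGPDWDEWAAQRWVFNGAYTENQGKLLDPYCRICHVFGRRLRDRFVNKMEGG
FRRVDIVVDYRWSMYRCYFCHPFLLGMARRLGAADAGIAVLQAMKIMIVESLQQCPKCHFAEKNRDELLP
DDQMYRVVKDASQQANKDFLLSCIGCHMWMVMTGWVPNPVSRNGWALEISALNDKQSMMACPNCHDRKVK
>gpcc_extracellular_omcB synthetic stand-in reference component
AYTMDCPMCHGNPALLGIEVQAGVPNIQAKGNTGMCKNCHMSNADREPYAEITNAVQYMDMIWNECPQCH
KFMVWILIVISGWNWANFNWVWDKSICLACHGIMDLPSIFVSMLLKEIGWQDLDIDCTACHMTGILEYMY
YPAFQYKGSQYMGNQYGCANCHSNYQFIKWTGTSQRRREPARKKVPMCSPCHQERITSKRVLGEVIQLVM
IASFMPMFCDSCHMRLYPRNLGWDDGDDNLISASWYAPCSACHTVPRTWQYEKMLAFKVVRKGKAKWQMC
SPCHTKLSQPWTDQSTMNNVYQLRDVYGPCEICHGDGSFVPMLQEVRWFAAPFTKKRSITCKRCHVNNAQ
>gpcc_periplasmic_gsu1999 synthetic stand-in reference component
RQLVPCTQCHKEPDQGRFKMDQTEWPVIGTPAMYNMPDFNMDRGWAPRYQISGFTMPRKELCGDCHSTEA
FVEKRTYVFSWDTEITGRNTDMIEIGLNFAEWYWYQYLAEQPMPTMDCNMCHVRVDPNWRWMEVPFYYIE
FKALYRPYNAGKKSSVQFYGRLIPPIAKNARESCNGCHENTFNPRSLINIWQQYWDTGWKEYRAWMFGFN
YVQKRQNKTNMGPDAKQKQRCGQCHLWETN
>mtrB_porin synthetic stand-in reference component
LWILAEYQNMDVSRMLMKAIVMPTIMTSYINTKLFIRFTKMNKFWFWNLLLWPTDVVIALDNQNQIWNNW
DIMQFWYIYTGEAPTSVMVYPPDRIPYFSVWLKGVEQRTVKAIRNYWFVALTYQYYSSRKPPSLPVWMVQ
MLWLRWAIYIFIMPAMPVPVRLEDAPLTMYFFNGYAKRAWIEKPAQTVEFASIVTLDSELKWWKIELQKG
IFMKYRIPMMRGVEKTRKSMMDLGYMEVALKRRIEELAQSGRSVYEQFLQSNSRKYFDFDTPRYGWKNMT
IGLRQGRAATYYSFLLMAVKYITVIKFDFT
>mtrA_periplasmic synthetic stand-in reference component
TQGLACYSCHYWQREDFRVVRDESRPNMEQMWATGLCTRCHIAMKVVFVTERPGIPRWANMFKDMAWRCM
DCHRPGIEIAFRTQQFAATISTSYWNQEDRCKACHMREFMIYLDGLEWDDRPPDLMELSESCGRCHMEIE
LPALTYTQKFIDNIQYWLMNNLLCPECHILYWRDIRRSTATFNSSMDLELDARFICWQCHEIGYDLAKFL
AVMPLESKETVPNFVFCPSCHYVPDDAAAWSIGDSSSLYWSKNEDNINCTSCHDEETPWFGTLERETILR
TQPGTRTPIRCEWCHIYAAQ
>mtrC_extracellular synthetic stand-in reference component
LMEVFCMVCHEADWINGKNKWNRGTRSEVKDSMEAPPQPWTCYQCHQLTLTDWEISERNFMTMGIFAYWV
YVTRMQTCYNCHKMKGTQVSMYDPWRQSVDTDIMVWDTPMNGTCDLCHWWPEEWYDQNWNWRNYNSVSYN
STQSWMSEECIMCHAGVKVTYMISAYFSRMIRAEGVTRITVGKVQCYTCHKGQSQRADATIKVKMEINWL
MYWAWPEVQLFCRSCHTTNIVLFSWTVITNTKITGQLNDNIEMTAWDCGECHIAEINRKIRNSNLTNKGY
NPQNVIIEYEPVLCTKCHTQGKDNFYMYMNLLIMWALYQQYFRIIFDYQECFWCHRAPRP
>cyc2_fused synthetic stand-in reference component
MPEPECPRCHRGRLVLRRANFQPPIVKIIVMFKKFLYQYNWRWKPWRSQREIYGPPLRLNATGMKMSDID
GDTVYKYYVASIRKNPLAALFFIPDVYKQPSNWKRVRLDEEWQPQWWWVAWADRARAVSRSRESMLPGKE
TVFTGGPQQQEFFRIQINTQKKFIEIEIKLPRFIIAKGTKRDMGGNVSTDSGRGPIFSATRREADFKISQ
FDVKNIANEPKYREIEWFDQSEFEQRDSTIDDDQQFMYYWGKRTLGVEIWPPYQNYGNEIPVGAVEFTRI
YMVIIQGRAI
>mtoB_porin synthetic stand-in reference component
ESAIKMLMAEKVDGKRYSISKEWNDMSDADIEQDTKLNQDSNQLQNMQNIMDDQVLDQYQNEMVVEVSQM
MGIYNDLVDSVIADGNFNMFEEVRGRGELTMVPTDTFYLVIDTQIWYVVSFIMMITDTIWVDWDPRVMQD
RYTIRAAQQTFSTAPYTMMSNKEQVTWTTENGTWGGLEDIRVALWDKGDITARDFSFQPGYWIELDALFY
AWEKRYFKYQGRVKAWPSKYAIADQYWRQQFVLYNQYNLPNAVLAEGDGNEAGTSMNWMLDYIAMIGRYV
AMPFWNWTLTSRSIMRVVSVSGSGQ
>mtoA_periplasmic synthetic stand-in reference component
FQWAMCVLCHLWGVSPIYRQMWPGMLKANFPDFPDTCEICHMQSAVTQAPWDEMWYTNIRRRKEPRACWE
CHQINVQEGDDGNDRKSWVKVRRTVNWYCRQCHNRIQSIYGRTPASGFAMIRWYSLQQTCKDCHRNVRNP
MMYGFYISYTNYWYALLDTYCFQCHLWPLSWRRMYGIGNMSNDAKGTIDMTCKQCHLYIIIGFPRPRSKA
LQYRMIAWKRPNCTLCHKMAMKNWWAIGFAQWYYGQGIRLGTDCMVCHVLMKTYTYDQQKWMRAKKEMKY
PWPERCLVCHIEFLT
>mtoC_periplasmic synthetic stand-in reference component
WEYNSCRKCHGMGAMPVVAYLRKRETTWMEVTIMSKAINNIANDNVWDTPDVSNWTSFSNQAVRANGYIN
TAEVWICMNCHGSWKALDWQQIDFQPLWFLYWNLLVPKIRYFWLDITMMNEDILVWWSDNPEGREGLKGF
TMQETFAGCPDCHAVDQTTQKEFFMDYGYWEATEDMPDSVKNMTVVMIQRYTDTNYQSTVKKKYKYGSTM
NTIFQWGQTMCKRCHRSRQP
>mtoD_inner_membrane synthetic stand-in reference component
SPIEQCYRCHKDVKNKDLFVRGMKQIQTWAMTVVPIYVRTGRSPDTQALAGWQPNNPFDQPANRTVWFFL
CQGCHNLFVESGTAKSLYLRLMYDINSSITSSFRMAKDYKQELVWFEMVQDAYNWVMAYNFQNPPCDTCH
IWADIDGLKPIKETPNMMMMTALMSRLATPDIYQDNSDSFFWTLAMGVARASDKQGTKMTCFNCHDGFYM
>foxE_ccyt synthetic stand-in reference component
WSQASCNMCHKGMIGVANIENYNYQYFRNSNISWVILLTTKKNLTGLVTAKFVGMNPTEARKWYVIQRNL
TKKPNWPIWTGDPQDMYNLLNLLGSYTRMEANYWNAAQSWALFENMMRPIDWNKAKLRQQNPVRALKVGL
DEMPDRKGDFSAMEMGESMVAGENTIPILRDTGYKRDQSQMFGLTELYDRWLTPSYEKGWAGWGQTEPPW
FDSNEKSPEWLSNDARLQTDLFMRAFPWVSKWLWFMKSGPCSTCHLGQQA
>foxY_accessory synthetic stand-in reference component
EDAKDTAGYQPVKSTQGPRSNRSWSLWVTSSDATSNVRYSVDDLQQYMPMKDVFSPSGLPWIRVFAIYPF
DVSASQATYRYIRAVPMIRMDSYITGVKDIDYLPDDWQLRWKWPAKDIGIFERYLNVQKLESEGSPTLQD
DLSYEAEYGVVYENLYGNKSNQTTYITFSQNSYEREGVWKATDNAMLYVGRYGFRSQSQQ
>foxZ_accessory synthetic stand-in reference component
EEWPYFNGDLQGRTRIQGRNIRNFFWGQWGWYFMMFVTYQLKKLFNMQISDPWSEKDNFYKVQPVKFVGD
DSIPFWESNWMVWFKQRFYEVNSFPSVQSAPQEPRSLFGGLWGSKGGAKWFDWEGSEYQYKWKYVKGINP
AQKNTSIQLINRKKGWTPYIASMEPNPWMWYSTPRSERAMEYAPGVFINRRIKPVRFPWESGVSQPVTEE
PIEGYNGTLN
>pioB_porin synthetic stand-in reference component
DVSWWRNEELNKFWSVSTTFQPRVDIATVQITNPYNWRYDERTNMVQEGWVYAINNRITLMEGQVGRIYQ
VMEVRYSVMYTSWEPAGGFRIVAKVADWYSLVSEQTKLVAAMSDWPTKSNNYIQNNPFVPYQWDVRWQPT
AFKLTANIWTIWNPWRETERILSKEMYRFRLNTMPVAILTDFFREIRRWVWEMQIQKRPIPSPLRRSLYI
FRVIQFFENQSDTWNAAENQDDPSNKFVKYSNVAPIFKYTTFSWMGRTKGQTYKKEQGQWPWDNQQDSSY
PETGIRTGPSRDQGYNYNNPPGYMFGEFLWMLVNN
>pioA_periplasmic synthetic stand-in reference component
NIGWKCLVCHYPFEDKLYILIKLARDLSWYLRQWARCPWCHEEGDNPFLKEMSATSWEPLLNNTTTGKCP
ACHQTTQPNRNDPSYNWGKTIYLAWPRWKMCLDCHFKGNKDRRVVRVDRKYFLKDGNDYLECEGCHQTTG
PGRNDPSTIIDQIKWPRQYKGTFCNICHITDRVNYEIDTYDTGRTWGMVTFAMEVCLMCHVNFVFLSPAF
GKAEGRAYQLDVGARLCDFCHISFFEPWSWVSAIDKYPTNAGKLPELTCRICHDGRSPAAQMMGAVKTKT
GPYYDYLDMFCRDCHPIKSA
>pioC_hipip synthetic stand-in reference component
KFMDRIRVNLQKQQQSADGRFGVEIRYADEFSLKRPWEYLWEWMPTYAIVVLIEEQRYDPRRDSFWRQEP
VNKMDWYTEVTMKLKRDPNAAGFKGIGAKKSVWGAENRLKRTGPRNLVWDAGWLVEQYYWTFRLIRTQVT
DSSEQRWTPVVILPSGNFRGGYNYSFFTTQQSQEWATFWD
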