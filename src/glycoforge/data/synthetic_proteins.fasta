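>EPO_SYNTHETIC synthetic stand-in for human erythropoietin (UniProt P01588); N-sites 24,38,83; O-Ser 126
CMCWMQYRQQMHMTQRPCDHVLQNQSFGMCLTLKYNQNNSPNETYEFLVVRGDLSYAYNY
EIEVANTDLHYHWWVKWMNYSHNRSSQSHCVFTLLLITWAQTSGKDRGQYDNYIHIRHLW
GDSQCSPVLEGPYMQMSHTKGMDKLMIYIWKFYCPVCVNDVKVQGM
>SIGLEC2_SYNTHETIC synthetic stand-in for human Siglec-2/CD22 (UniProt P20273); 11 N-sites 17,33,49,67,91,112,135,158,179,201,223; Lys66
LVYKSYRFWLRYECPINASPELTDLACAHMPYNVTPQWKYEWDIIHQLNATTALKWNIDC
KTVIEKNKTWCYVYRAGPYSRRWTTDIAMLNVSPHDAEWQYSKQNKNCASENKSKYIVKC
DMYRTRRKTYTSATNITWYHFYQTYKNQKKWCGNEDKNWSEFQQVKKTCSPCMVATCDNV
SYWPKNYYEMGFKFDATLANNQTWHASGIIWAGRGFVNALIFNSSWYHIPHRIFGVWTLT
>GPC1_SYNTHETIC synthetic stand-in for human glypican-1 (UniProt P35052); HS O-Ser 45; C-terminal Ser 120
YGLCIGNSCCHLWVHQGLKVDIGWWVIMEKPWYGNENIPVRSSPSYNHEFENGDLLQTVM
MHSCAQRARLWWSDNNLYKTRKRQLNDVYNTKAHCGEQCTYTSWHVEVFKPESFIHYYCS
>BIKUNIN_SYNTHETIC synthetic stand-in for human bikunin (UniProt P02760 fragment); CS O-Ser 10
FKRHDNRSRSWDEKDTRKWFVMDDDRCIHEVHNWAMVWACRPMQQICPATVSMEQGNVWR
TFWSYVNSVMIVLEVMMGNAMDSQIQGQMLPNWCQWHWGS
>ADG_SYNTHETIC synthetic stand-in for human alpha-dystroglycan mucin fragment (UniProt Q14118); core M3 O-Thr 30
MMMGQGFDSWDHPFATDNDFVYTYKSCQVTMEISFDLSIYCWPCIEWRPRRAKECQNMPI
MMYYRAHGEGPTEKQIEGVNLVNECACNHT
>MAN1A1_SYNTHETIC synthetic stand-in for mouse Golgi mannosidase MAN1A1 (UniProt P45700 fragment)
DDSFLAWTHYHLFLMSYCLYYHFDHIKSLLDQFIDIPWWPTMTANYLMCIWRFNAEFDCD
NIFMSADCTKCASVIQYTCMEHACCSSYTEEEDHQHWLDYAECKYVLKIYPLATRWHFKQ
YIYARYYAMKTLGCMKNVVYHYIETWPFYD
>ALG1_SYNTHETIC synthetic stand-in for human mannosyltransferase ALG1 (UniProt Q9BT22 fragment)
GICKGFWPDADMAIDAQTSEFKRMCQNHMSPNPMHDNTRCIRLCDVHHDNYFNWVSDQLM
EWLFALQATRANWDYQYMLPMLHQGNPLIWVERDDAHMIALWACHAEQEWMKLNHATHTS
QRRHAENINKYNEAKVHKYQ
>BC2LC_SYNTHETIC synthetic stand-in for B. cenocepacia lectin Bc2L-C (UniProt B4EGV4 fragment)
TTTHRYDKQHWRPDHQTFTGGQAKYTDCNGMMFRYEELPTSTPRRCKCSKWGETPRESIN
NNTTVPFFKCCQQDGLRNGLYAFIYLQFDRNYIHSACEYAFAHLERFSSG
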