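>papain
IPEYVDWRQKGAVTPVKNQGSCGSCWAFSAVVTIEGIIKIRTGNLNEYSEQELLDCDRRS
YGCNGGYPWSALQLVAQYGIHYRNTYPYEGVQRYCRSREKGPYAAKTDGVRQVQPYNEGA
LLYSIANQPVSVVLEAAGKDFQLYRGGIFVGPCGNKVDHAVAAVGYGPNYILIKNSWGTG
WGENGYIRIKRGTGNSYGVCGLYTSSFYPVKN
>syn_cathepsin_L1
LQMIPKSHVKKHVISGYGGSFERIIPWNELTLKKAHMFCTNVLVRTYEITGYNALLQHPN
IKEAVDWWQAPAVTPLVIQASIGSCMAFQRSRTIEGINKKRTGNLLKYSNHKLLFCDCRS
EGCYGGLMWVSLQLVAIYKIAYTYTYPQEDLQGICRSRIKGPYSMKTDGVNQVQQNNVGN
ALASIVHQPVSVAHEAFMKDYQIYNGGIFVGECGWKMAHAVAAVGYGPAYQLIFNSFGTG
LNDGHMKRNKGGTPNELGQLGCYTAKSYPVFN
>syn_cathepsin_L2
IKEAVDWWQAPGVTPLVIQASVGSCMAFQRSRTIEGINKKRTDNLLKYQNHKLLFCDCRS
EGCYGGFMWVSLQQVAIYPIRYTYTYPWEDLLGICTSRAKGPYMMKTDGVNQVQQNNVGN
ALASIVHQPVGVAHEAFMKDYQIYNGGIFVGECGWKLAHAVWAVGYGPAYQLIFNSFGFK
LNDGHMFRNKGGFPNELGSLDCYTAKGYPVFN
>syn_cathepsin_B
LTQWQMLREYIDIVYFLSVGIECKDHSKGFNCDFIDYEGDHCTHPWKFWKAMHFRGTNMW
EKIPELVDWRFHGAVTGVKNQEYNGSCPFFSAVQVIIGIIKIATGNVNEDSERGLWICPL
IYYGCNGGYPWSAMFLVAQYWRHHRWTRPPEGVQRYCRSQENGPRAAPTFWPEVPHHLKS
YYFLFQQFKRLPDGVRQVQAYNEGKWLYFIANQPVSVAKQAMGKDFGCYYGGKFNGSFGN
KGFHAHAVSGAGPNWILAKNKNGIGWGMNPCICIKRDQGNDKSVCGLPFESWDGGKN
>syn_cathepsin_F
TPMIWSWYQKVAVTPVKDQGSWGNCWASKYWTPIPARIKLGTGNEEETGCAETLWCDCRP
CWCNGRLMLSAFSLGNIYGIHYRNMNLYESPQETIRSAMKAAYAMQFHGCRQVQCYNSLA
LLYCTCNIPVTNALDTAGKHYCNMRGGITVMSRGNKLDHVVGAVGYGMNTILCKNRNGTV
WMWNGCIRSIRGGGNFMGRFGHFFPSFPPVKA
>syn_cathepsin_O
YWPHVFWWQRFAVTMVKNQGECGSCWSFSAFIRIIPQIKIRTGNLEQYSEQEWLDYDQDS
VDCNGSDVWSTFIRVRQYGIVYMLNYPYEGVRDEQRRREKGPYTSDWPCKRWSQPYTFTR
IHYSTFVQTVIVALHDKGQWAQYYPDGETGGPCGNKLCHDTAFVGNGPTYVEIKNFWGVG
WGENGYSPNGRGTGNQYGVCILYSESLVPEWN
>syn_cathepsin_K
IPEEVDCRQMTISTWVTNQGSCGSCYAPAAVVMICGIIKICTGNLNEYREQHLKAAYRRS
ETHQGGSLTAALNNHAQYGYHYRNTYTYEGRQWYFRSREIGPYRPKTDIVWPVMPNNLSD
LLYEIPIYPVGWSWFAADKDFMRYRGRIFHLPPGNKVQHAYRGYGYGPHYILIKNSWTDG
EGESGVIPWKIVTGCSYGGGGLYGYLGFPVKQ
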