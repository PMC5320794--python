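# STOCKHOLM 1.0
#=GF SQ 8
CBM1_syn1 DLNACEADVYILEGDSALSCYEMLWTFSTYLGCVSD
#=GS CBM1_syn1 AC CBM1_syn1
CBM1_syn2 DGNACVADVYILPGDSALSCYEMLWNFSTYLGCVKD
#=GS CBM1_syn2 AC CBM1_syn2
CBM1_syn3 ILNACVADVYILPGDSDLSCYEMLWNFSTYLGCVKD
#=GS CBM1_syn3 AC CBM1_syn3
CBM1_syn4 DLNACSADVYILPGDSQLSCYEMLWNFSTYLGCVKD
#=GS CBM1_syn4 AC CBM1_syn4
CBM1_syn5 DENACVADVYILPGDSQLSCYEMLWNFSTYLGCVKD
#=GS CBM1_syn5 AC CBM1_syn5
CBM1_syn6 DLNACVADVYILPGDAQLYCYEMLWNFSTYLGCVKD
#=GS CBM1_syn6 AC CBM1_syn6
CBM1_syn7 DLNACVFDVYIAPGDSQLSCYEMLWNFSTYLGCVKD
#=GS CBM1_syn7 AC CBM1_syn7
CBM1_syn8 DLNACVADVYILPGDSQLSCYEMIWNFSTYLGCVKD
#=GS CBM1_syn8 AC CBM1_syn8
//
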