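# STOCKHOLM 1.0
#=GF SQ 14
AA9_syn1 HVSFGTASSLGGGKLMYSPGYFENGAFLVPALDETLLLFAEQEIAGSEGTLTPRCPLLTINAIGDHSIYNNPQRWGFKCWFQGTPNPFKTVNNDESSTTTTSTTTTSTSTSSTSSTSTTVMITPNI
#=GS AA9_syn1 AC AA9_syn1
AA9_syn2 HVSFGTASSLGGGKTMYSPGYFENAALLVPALDDTLLRFAQQEIAGSEGTLTPRCPKLTINAIGDHSIYNNPQDKGFKCWFQGEPNPFDLVVNDESSTSTTTSTTTSATSSSTTATTTTVMETRNI
#=GS AA9_syn2 AC AA9_syn2
AA9_syn3 HVSFGTASSLGGGKLMYSPGYFEMAALLVPHLDEELLLFAEQEIAGSEWTLTPRCPLLTFNALGDHSIYNDPQDNGFKLWFGGTPNPFDTIVNDETTSTTTTTSTSSTTSSTSSSSTTSVMETPNI
#=GS AA9_syn3 AC AA9_syn3
AA9_syn4 HVSFGTASSLGGTKLMYSPGYFENAALHVPALDETLLLFAEQEIAGSEGTLTPRCPLLTINAVGMHSIYNNPQDKGFKCWFQGTPNPFDTVVNDESTTTTSSSSTSSTSSTTSTSSTSSVMETPNI
#=GS AA9_syn4 AC AA9_syn4
AA10_syn1 HFLTLMGAAEAAWPKLFHNGQILFDEVARS------DKSAPSLRFGEIEHVDHGVPKYTLVRNKTHKVAKLVFSQGRPYHLEAEVNKFTDNLNPGSTSTSSASSSTSSSSSSSTSTASSWLPPEAK
#=GS AA10_syn1 AC AA10_syn1
AA10_syn2 HFSTLMGRAIADWPKLTHNGQILSVEVARS------GKSAPSLRFGEIEHVNHGVPKYLLVGNETHKVAKLVFSQGRPYHIEAEVNKFTDNLNPGSTTSTSSSTSTSTTSATSSSSSSSWLPPEIK
#=GS AA10_syn2 AC AA10_syn2
AA10_syn3 HFATLMGRAIADWPKLTHNGQILSVEVARR------DKSAPSERFGEIEHVNHGVPKYLLVRNKTHKVAKLVFSQGRPYHIWAEVAKFTDNLNPGTTSSSASSTSSTSTSSSTSTTTSSWLPQEAK
#=GS AA10_syn3 AC AA10_syn3
AA10_syn4 HFATLMGRAIADWPKLTHNGQTLSVCVLRS------DFSAPVLRFGEIEHQNSGVPKYLLVRNKTHKVAKLVFSQGRPYHIEAEVNKFTDNLNPGSTSSTTTSTSTTTSSTSTSSSTTTSLPPEAK
#=GS AA10_syn4 AC AA10_syn4
AA10_syn5 HFATLMGRAILDWPKLTHNGQILSVEVARS------DKSAPSLRFGEIEHVNHGVPKYLLQRNKTHKVAKLVFSQGRPYHIEAEVNKFTDNLNPGSSSSTTTASSSSASTTSTSSSSSSWLPPEAK
#=GS AA10_syn5 AC AA10_syn5
AA10_syn6 HFATLMGRAIADWPKVTHNGQIRSVEVARS------DLSAPSLRFGEIEHVNHGVPKYLLVRNKTHKGAKLVFSQGRPDHIEIEVNKFKDNLNPGTSSSSSSSSSTSSTSSSSSTTSSTWLPPEAK
#=GS AA10_syn6 AC AA10_syn6
AA10_syn7 HFATLMGRAIADWPKLTHTGQGLSFEVARS------DKSAPSLKFGEIEHVNHGVPKYLLVRNKTHKVAKPVFSQGREYHIEAEVNKFTDNLNVGSSSSSSSTSSSSSASSSSTTSSSSWLPPFAK
#=GS AA10_syn7 AC AA10_syn7
AA10_syn8 HFATGMGRKIADWPKLTHNGQILSVEVARS------DKSAPSLRFGEIEHVNHGVPKYLEVRNKTHKVAKLVFSQGRKWGILVEVNKFTDNLNPGTTSSTTSTSTSSSSASSASSTSTTWLPPEAK
#=GS AA10_syn8 AC AA10_syn8
AA11_syn1 HSRDVSTLVAAAGFEMANEGQAGVLSPNEN------AVWTAHGDPGSGTSDSTENPPNCPPSSVRHTVEAPFSVIGGKPDIDFSINSFILFFHLCTSTTSSTSASSTTTT----TTSTTRNGASDD
#=GS AA11_syn1 AC AA11_syn1
AA13_syn1 HCVGGTPEKTIRCRSSQIAGLREGLRVDES------PRYVTSIPEGRRR---ALLPIMRISVIDRHYDRSVDFYDGEGKREVFSANDFFAGGRKATSSSTTTSTSTTSTTTSTSSSSSTYYVFIFD
#=GS AA13_syn1 AC AA13_syn1
//
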