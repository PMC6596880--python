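# frozen k-mer score panel; expected scores computed by
# scripts/make_panel_fixture.py (naive PWM arithmetic)
sequence	expected_score
GTCTAGTAGGGAAAGTTCTACAC	-26.302600
ATCATGGTAACTCCGCCGGCACC	-24.591805
ACGGATATAGACGGGATCGCCAA	-29.683422
TTTGGCTTAGCTTCGAATGCCCT	-17.653206
ACTTAACGGTGAAATCATATCAC	-13.598647
ACGGTCCAGACATACCCTCGCGC	-12.930804
ACCGAGTAGTAGTGTTGTGAGCC	-21.088728
TAAGCTTTGGCGGGCAGGACGAA	-16.821760
CTGAAGGTTCCCCCGGGTCAGCC	-20.421880
ACCTGGCCACCGCAGGCTCATGC	-25.451074
CTCTAAGCCACCTTGACAGGCGA	-12.104287
TCCATGATGTGTAATCGCTTGAA	-15.795058
CGGGATTATCACTCTCACCCGTT	-15.067355
TTCGCAATGAGGCCTTGAGTTCT	-22.639280
CGTTAGTGTTAAACTAGGGGCTT	-15.821760
TCACTACCCAACGATTTTTCGCC	-17.191100
ACTTCGCCTCCCTCACAACCAGG	-16.071801
CCAACGAGGCGATTCGAGGTCCC	-30.406582
CATATTCATTCATAGTGTTCCTT	-17.210984
TTGGCGATTAATCGACACCGAGC	-9.597759
GCGCTTCACCCCATTGGCAGAAC	4.086870
TTGCTCGATAGAATTTATCGACT	-7.603716
AACGATGTAGACACCAGATCGGC	-27.520176
ATTCCTATGACTTCAGACTTAAG	-16.389283
CTTCGTACGGGGGCTGGACATAA	-25.475782
CATATTCACACGCAGCGCATCAA	-10.395580
GGCCTTTTAATCCATTCATCGAG	-15.596875
ACGGTGGGTGATGCCCGCGGGTT	-10.992038
GGGGCCCCCCTTATATGAAAGGA	-9.967337
ATTGACTCAGCTATATCCATTAC	-8.348229
CCCGACGAACCGTCCCACTGTAT	-10.015800
GCAATTCCAGGCGGAAACATCAT	-16.359402
ATCTGTGCTCGGGAATCTCGGTG	-9.650119
CGCCGTACTTCCTTCATTTAACC	-14.383745
GGGGGTATAGGGTGTACGTCGGA	-31.546365
CTCAACCCGTCACAGTGCGAGAT	-17.157958
ACGAAATTTTAGGAGGACGCCCA	-26.817173
GAGGCTCGTGGTGGACGGGCTTT	-31.289563
CTGTAGTTGGGTTCTAGTGCTCC	-18.951224
TTTGGTGACCCCGCCCGCACCTT	-5.751723
GCCGGAGGACCGGTTTGCTGTTT	-13.621247
GGCAAGTAACGCTCAACTTGCAC	-17.189370
TGAGGATACCTCTCTACTAACCC	-9.901658
AAAGCATCAGACAAGTACAGTAC	-8.201555
CTTGTCATCGCTTTCCCACCTTA	-14.166589
TTCTTGATGCATAAGAGAAGGCG	-2.216454
GGTTTAAGCAATGTGACTAGTAG	-5.557592
GCTGTTTCTGAAAACCGGCACTC	-24.168500
ATTAGCGGGCTAATCATACACGG	-26.418077
TCCTCGCATAGCGTCTTTGGAGT	-5.685330
CAACGCGCTCAAAGTTTTCGGTC	-11.136541
ATAGTTAATGACTAAAGGAAGTG	-18.214078
TAAGACAAACCCCAGAGGTATTC	-33.500460
ATGGCGGCGGTTAGGTTAAACCC	-18.456628
CCACCGCACGCACATCCGTATCT	-25.887591
GTCGCCCGACTGATTAAAACGGA	-11.672594
GATAGTTCAAGACGGCGCTAACC	-24.275415
ATTGCCCCTGGATTACTTGACAC	-18.390171
CCTCAGTTCATACCGTCTATTTC	-7.272301
GAAATACGAGTCTCAGTTTATTT	-27.288842
GCTATAGGCTCTCAAAAGTGTGG	-18.085837
GCTAGAACTAGCGAATCAGTTCG	-28.975902
ACTAACCGTCCCCCAATAATTAA	-14.067915
TAGAGCCCCTACGTAACGGCGAT	-26.265409
CTCGCTAGCAGGGCGAGACCCGC	-28.508680
ACCATTCATCGCGTCCGACTAAT	-18.577111
GTTATCTTCCCGTGAAGCAAGTA	-5.114894
ACGCTTCATGCGTGTCTACAATC	-19.767795
GCAGGCCATCGTCGGATTCAGGC	-24.256420
GCTAGGGGGGGCGGTCTAGCCTA	-30.740006
GTGAGACATAAGCCTGTTGCTTC	-26.966913
ATCCGAGTTTAAACGTGGGTCAA	-26.712821
GGTGATTTTTGTATCCAGCTGCT	-18.656434
TTGCGCGGTTCCGTTCTCGGCAT	-4.620479
CTAACATTTACTATACGGACCCT	-12.429443
AGCTGGTTATAAGAACCTCAAGT	-24.296067
TAGGCTGAACAATCACATTCAGA	-23.782489
TGTGCCCTGTTTAAATAGTGTAA	-12.383087
ATCCTGCGCTTATTAGTCTGAGC	-6.427834
CTGGCCGGCCCGCGTGGACACCG	-25.016827
TTTTTTGTTCCATTTCACAGACT	14.617188
CTAGCCTCTTTTTTCTGCAGAAC	13.263551
TCTCCATTTCTTTATAATAGGTG	10.849587
TCCTTCTTCTCCTTCTACAGGAG	17.313181
CCCTGCCTTTTTATTCCCAGGGG	13.740710
TCTTGTTCTCTTGTTTCTAGGCG	14.564827
TCCTTGTTCCGCCTCATTAGAAT	7.861082
CCTTCTCCTTCCGCGGACAGTTT	6.174468
CTTTTTCCACGTGATAGCAGACC	6.490411
TCTATGTCTTACCACTCTAGGTA	8.669433
TCTCCCACTCACTACCTTAGTAT	5.747047
TTTCTGCCCCGTTCTTGCAGGAC	13.304193
TCAGTGTGCCTCTCTCCTAGTGA	5.748042
CTCTCTTTCCTTCGCCTCAGATT	13.476680
CTTTTGGTTCCGCCCCCCAGGAT	10.904209
TTCTCCTTCATCCTCCGCAGAAA	13.596974
GGAGCGCGGATTCGACTCAGTAC	-6.201555
TTCTTTCCAATTTTCCCTAGAAC	12.535681
TTCTTCATCTTTTTTTCTAGCGA	15.050254
TTATCTTTTCCTTTCTATAGATA	15.037763
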