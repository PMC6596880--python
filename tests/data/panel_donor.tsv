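# frozen k-mer score panel; expected scores computed by
# scripts/make_panel_fixture.py (naive PWM arithmetic)
sequence	expected_score
TGGTGAAAT	-13.419922
CAATGCGCC	-20.367393
ACCTTTCGT	-10.076966
GGGGCTTGA	-7.595145
GAGCGAGGT	-9.651545
TGGAATTCC	-22.167721
CTCATGACA	-10.402097
AAACCCCGC	-18.042262
TAACGTAGA	-15.652519
CCACTGTAT	-10.232172
TTAAGAAGC	-14.720881
CCATAGAAT	-17.384819
ACCATCCTG	-14.689332
CTAGCGGCC	-11.857507
GGAAGTCCT	-22.762143
CCTGAAGAT	-9.057241
TTCCATGTC	-26.088417
AATCATACT	-17.929503
AGTCCACGG	-17.104493
CTTTGGCGC	-17.560940
AGCGAGACC	-10.331802
TACAAGCCT	-21.378040
ATTGTCAAG	-0.568852
TAAGAGATA	-8.516126
AGCCCCAAC	-21.562712
TCGCGGCAA	-19.251067
CGCAGGTTG	-21.340072
ATAAAAACT	-16.892683
TAGGTCCGA	3.672145
ATAAACGAA	-23.301411
ACGACCCAC	-20.459060
CGGTGTAAA	-16.377439
CCCGGGGTC	-11.594472
TGTAAATCA	-22.737052
ATCTCCTCC	-24.962409
CCGGTGATG	4.621669
CGACTAAGC	-4.069001
GGTGACTCT	-13.478766
ACCTGGGCC	-21.944487
GGCGCCAAA	-12.485192
ACGAATACT	-16.603459
CCCGGCCAG	-13.339961
GTGCATACT	-17.399926
TGGACGTAG	-19.362792
GACGCCAGT	-5.343606
CATGGGCAC	-8.943236
GCCCCTAAC	-22.658739
AAGAGACGA	-10.931894
GATCCGAAA	-17.784863
ACACTGTGG	-7.839927
AACTAACGC	-16.184281
ATTTCGAAC	-19.107385
AGGTCACGT	-12.539577
GTCAACGGT	-20.055827
TGACAGCGA	-19.933805
ATTACCACC	-21.347699
TACCCGAGA	-15.704986
CGCATTAAC	-11.669824
GGCTAGCAT	-22.329184
AGAGTCTAG	-3.076647
GAAGTCAAT	2.066199
TAATAGCTA	-21.606859
AGCTAAAGC	-15.154534
GGGGCCGCA	-11.175089
TCTGCAAAA	-9.589736
ACGTCAGCC	-17.501544
AGTCGACGA	-16.563925
CCCATTGCT	-13.402097
TCTAACATA	-22.631559
AGACGTTCG	-22.676170
GGGAGTATT	-16.029976
TCAAAAGGA	-18.352664
CCTATCATC	-10.999132
TTGTGGCGC	-15.613407
TTTCGAGCC	-21.493470
CCTATACTT	-9.866044
GACGCGAAG	-8.171337
CAACTCCCC	-11.992353
GGCTAGCTC	-23.955967
CCCTTGGTC	-12.595920
CCTGTGAGG	4.861764
CAGGTAAGT	12.736224
TAGGTATGT	8.343907
AAGGTACGG	8.448989
AAGGTGAGT	11.507600
CTGGTAAGG	9.497352
AAGGTCGGA	5.716539
CAGGTACGT	9.606941
AGAGTATGC	2.959563
CAAGTACGG	5.234670
CAGGTCAGA	8.386390
CAGGTAAGA	11.244371
CTGGTGAGG	8.394259
CTGGTAAGC	9.125383
CAGGTAGGC	8.787514
CTGGTAAGC	9.125383
CAAGTGAAT	4.743084
AAGGTAGCT	6.030749
AAGGTGAGT	11.507600
CAGGTAAGG	11.703803
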