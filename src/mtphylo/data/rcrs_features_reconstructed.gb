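LOCUS       NC_012920              16569 bp    DNA     circular PRI 19-MAY-2011
DEFINITION  Homo sapiens mitochondrion, complete genome (rCRS); reconstructed
            feature table only, sequence block omitted.
ACCESSION   NC_012920
VERSION     NC_012920.1
COMMENT     Minimal reconstruction of the revised Cambridge Reference Sequence
            (rCRS) annotation for structural partitioning: the 37 genes (13
            protein-coding, 2 rRNA, 22 tRNA) and the D-loop, at their published
            coordinates. The nucleotide sequence is not included; supply the
            reference sequence separately as FASTA when residues are needed.
FEATURES             Location/Qualifiers
     source          1..16569
                     /organism="Homo sapiens"
                     /organelle="mitochondrion"
     D-loop          join(16024..16569,1..576)
     tRNA            577..647
                     /product="tRNA-Phe"
     rRNA            648..1601
                     /product="12S ribosomal RNA"
     tRNA            1602..1670
                     /product="tRNA-Val"
     rRNA            1671..3229
                     /product="16S ribosomal RNA"
     tRNA            3230..3304
                     /product="tRNA-Leu(UUR)"
     CDS             3307..4262
                     /gene="ND1"
                     /codon_start=1
     tRNA            4263..4331
                     /product="tRNA-Ile"
     tRNA            complement(4329..4400)
                     /product="tRNA-Gln"
     tRNA            4402..4469
                     /product="tRNA-Met"
     CDS             4470..5511
                     /gene="ND2"
                     /codon_start=1
     tRNA            5512..5579
                     /product="tRNA-Trp"
     tRNA            complement(5587..5655)
                     /product="tRNA-Ala"
     tRNA            complement(5657..5729)
                     /product="tRNA-Asn"
     tRNA            complement(5761..5826)
                     /product="tRNA-Cys"
     tRNA            complement(5826..5891)
                     /product="tRNA-Tyr"
     CDS             5904..7445
                     /gene="COX1"
                     /codon_start=1
     tRNA            complement(7446..7514)
                     /product="tRNA-Ser(UCN)"
     tRNA            7518..7585
                     /product="tRNA-Asp"
     CDS             7586..8269
                     /gene="COX2"
                     /codon_start=1
     tRNA            8295..8364
                     /product="tRNA-Lys"
     CDS             8366..8572
                     /gene="ATP8"
                     /codon_start=1
     CDS             8527..9207
                     /gene="ATP6"
                     /codon_start=1
     CDS             9207..9990
                     /gene="COX3"
                     /codon_start=1
     tRNA            9991..10058
                     /product="tRNA-Gly"
     CDS             10059..10404
                     /gene="ND3"
                     /codon_start=1
     tRNA            10405..10469
                     /product="tRNA-Arg"
     CDS             10470..10766
                     /gene="ND4L"
                     /codon_start=1
     CDS             10760..12137
                     /gene="ND4"
                     /codon_start=1
     tRNA            12138..12206
                     /product="tRNA-His"
     tRNA            12207..12265
                     /product="tRNA-Ser(AGY)"
     tRNA            12266..12336
                     /product="tRNA-Leu(CUN)"
     CDS             12337..14148
                     /gene="ND5"
                     /codon_start=1
     CDS             complement(14149..14673)
                     /gene="ND6"
                     /codon_start=1
     tRNA            complement(14674..14742)
                     /product="tRNA-Glu"
     CDS             14747..15887
                     /gene="CYTB"
                     /codon_start=1
     tRNA            15888..15953
                     /product="tRNA-Thr"
     tRNA            complement(15956..16023)
                     /product="tRNA-Pro"
ORIGIN
//
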