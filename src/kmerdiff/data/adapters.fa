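>TruSeq_read1
AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
>TruSeq_read2
AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA
>Nextera_read1
CTGTCTCTTATACACATCTCCGAGCCCACGAGAC
>Nextera_read2
CTGTCTCTTATACACATCTGACGCTGCCGACGA
>TruSeq_universal
AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT
>TruSeq_indexed
CAAGCAGAAGACGGCATACGAGATCGGTCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT
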