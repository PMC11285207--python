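>N_DOMAIN motif=79-117 hinge=31-52
FVKDVMSDEAQCTECKYNTHALPVVTTEGNPFYPDMMFEATVNVSSLAAKFIECVMQEATFELKGKFNKLKFRPQIECMRGAQKDLTKKRVDAQLRDKQNEMIFQSLIFGGLATSVDSSRQHDIRLNQWGWIHIW
>C_DOMAIN allosteric=45-80
WGINDWNEKDKGECKQMLSGKMGILDWKPRPVYSDSSQNPVWYSNYQPDCRGWMWKQAVHCHHDMIISAPPGAAQNNWDAPPRSM
>TLR5_MOTIF_ALT
MDVAKTPMCKKRVFMQTRDLQGEMIHQPWCTFASVTHQS
>C_ALLOSTERIC_ALT
ETERVGNGWMYKSDVMGTQDWIICYKYGAAQVNWDK
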