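allele	variants	functional_status
*1	-	normal
*2	c.36_37insGGAGTC,c.415C>T	nonfunctional
*3	c.415C>T	nonfunctional
*5	c.52G>A	uncertain
*6	c.36_37insGGAGTC	uncertain
*7	c.101G>C	uncertain
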