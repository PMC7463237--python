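hgvs_c	rsid	protein_change
c.36_37insGGAGTC	rs869320766
c.52G>A	rs186364861
c.101G>C	rs766023281
c.415C>T	rs116855232	p.Arg139Cys
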