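>DEMO1 synthetic substrate with internal serines
MAGTLVKDWSAEQIRAGHELPKSTGDVNKFEQLAR
>DEMO2 synthetic substrate with an N-terminal-region serine
MVLSPADKTNVKAAWGKVGAHAGEYGAEALER
>DEMO3 synthetic substrate with basic-residue/serine motifs
MDEKSGLLTRQSAPNVKGGSELIKR
>DEMO4 synthetic serine-free decoy
MTTAGLVNKPEGHQLFDEIRAEGYLVK
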