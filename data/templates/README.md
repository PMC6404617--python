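# Template structures

Coordinate files placed here are used by the optional template-based
checks. They are not redistributed with the package.

To run the SOD1 panel-concordance test, fetch the wild-type human SOD1
entry (PDB id 2v0a, 1.15 Å) from the wwPDB and save it as `2v0a.pdb` in
this directory, e.g.:

    curl -o 2v0a.pdb https://files.rcsb.org/download/2V0A.pdb
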