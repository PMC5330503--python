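# data/

`reference_pdb/` holds the 25 PDB entries used by the worked examples
(cel48F, calmodulin, human thymidylate synthase).  It is not distributed;
populate it once with

    python scripts/fetch_reference_structures.py

(network access required).
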