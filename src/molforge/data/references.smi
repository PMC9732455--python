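# Named reference structures bundled with molforge (SMILES<TAB>name).
# External database records are deliberately not redistributed here; see
# molforge.chem.load_reference_smiles.
NC(=O)c1ccc(NC(=O)c2ccc(C(C)(C)C)cc2)cc1NC1CCCNC1	PCW-A1001
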