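# Deposited coordinate files

The acceptance tests that reproduce published c-KIT quadruplex numbers
(cleft widths, loop torsion tables, water counts, topology regression,
NMR-bundle compactness) read coordinates from this directory. PDB
depositions are not redistributed with the package; download them and save
as lower-case stems:

    data/deposited/2o3m.pdb   # NMR bundle of the c-KIT promoter quadruplex
    data/deposited/3qxr.pdb   # BrU-substituted crystal form, 1.62 A
    data/deposited/4wo2.pdb   # native crystal form, 1.82 A
    data/deposited/4wo3.pdb   # native crystal form, 2.73 A

mmCIF (`.cif`) works too. Without these files the corresponding tests in
`tests/test_acceptance.py` fail with a message pointing here; every
synthetic check runs regardless.
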