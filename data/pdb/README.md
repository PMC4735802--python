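# Crystal-structure inputs (not redistributed)

The survey-regression tests and acceptance targets t1–t3/t6–t7 need the
published K-channel crystal structures.  They are not bundled; place the
files here manually, e.g.:

    curl -o data/pdb/4HYO.pdb https://files.rcsb.org/download/4HYO.pdb
    curl -o data/pdb/2R9R.pdb https://files.rcsb.org/download/2R9R.pdb
    curl -o data/pdb/1K4C.pdb https://files.rcsb.org/download/1K4C.pdb

Use the tetrameric biological assembly, flattened to a single MODEL, when
the deposited asymmetric unit contains fewer than four channel chains
(1K4C).  Non-channel chains (Fab fragments, toxins) are dropped
automatically: the pipeline keeps the chains carrying the T-V-G-Y-G
selectivity-filter signature.  `.pdb.gz` files are also accepted.

When the files are absent, the dependent tests skip and the acceptance
report omits the corresponding target keys.
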