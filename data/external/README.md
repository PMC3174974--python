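# External reference data (user-supplied)

The library performs no network access.  Two groups of acceptance checks
in `tests/test_acceptance.py` compare against published reference data
that must be fetched once by hand into this directory:

1. Deposited crystal structures, as PDB files named `2QD0.pdb`,
   `3TBN.pdb`, `3TBM.pdb`, `3TBO.pdb`:

   ```
   for id in 2QD0 3TBN 3TBM 3TBO; do
       curl -o data/external/$id.pdb https://files.rcsb.org/download/$id.pdb
   done
   ```

2. The published supplementary CISD sequence collections (aligned FASTA,
   record names following the underscore-joined convention parsed by
   `cisd.io.parse_record_name`), placed under
   `data/external/supplementary/` with a `.fasta`, `.fa` or `.txt`
   extension.

Without these files the corresponding acceptance tests fail with a
message pointing here; all other tests are self-contained.
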