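# GenBank exports for the accession-anchored checks

The full-length HoxC9a comparisons re-run against the study's deposited
records. This package performs no network access; export the four records
once as plain FASTA into this directory:

| accession  | record                                   | file              |
|------------|------------------------------------------|-------------------|
| MN584925   | red crucian carp (RCC) HoxC9a, genomic   | `MN584925.fasta`  |
| MN584926   | common carp (CC) HoxC9a, genomic         | `MN584926.fasta`  |
| MN584927   | allotetraploid (4nAT) HoxC9a, genomic    | `MN584927.fasta`  |
| BC165307   | zebrafish HoxC9a cDNA                    | `BC165307.fasta`  |

For example:

    for acc in MN584925 MN584926 MN584927 BC165307; do
      curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text" > ${acc}.fasta
    done

Then run `polyhox validate --fasta-dir data/accessions` or the
accession-anchored tests in `tests/test_acceptance.py`. Without these files
those checks report which exports are missing.
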