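# Accession data (optional, user-supplied)

The accession-based checks in `tests/test_acceptance.py` reproduce
published clade statistics and tip-date estimates from the deposited
American mastodon consensus mitogenomes. Those sequences are not
redistributed here; to run the checks, place the following files in
this directory:

- `alignment.fasta` — GenBank accessions MN616941–MN616973 plus
  NC_035800 and EF632344, aligned (e.g. with MAFFT/MUSCLE), VNTR region
  masked with Ns, sequence ids matching specimen names (e.g.
  `UAMES 11095`).
- `clades.tsv` — tab-separated columns `tip`, `clade` (A, Y, G, M, N,
  L) and `flag` (empty, `alberta` for RAM P94.16.1B, `virginia` for
  ETMNH 19335/ETMNH 19334), from the study's supplementary tables.
- `tip_dates.tsv` — tip-date table (`id`, `status`, `age_bp`,
  `lower_bp`, `upper_bp`, `prior_shape`, `prior_scale`): calibrated
  median ages for dated specimens, `estimated` for undated ones.
- `topology.nwk` — a starting tree topology for the dating run (e.g.
  the published maximum-likelihood topology).

Without these files the corresponding tests fail with a message naming
the missing input; all other tests are self-contained.
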