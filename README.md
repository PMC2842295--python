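# dwmkit

Dinucleotide weight matrices (DWMs) for transcription-factor binding-site
modelling: a DWM generalises the position weight matrix (PWM) by storing a
4×4 joint probability table for *every* pair of motif positions, capturing
correlated columns at arbitrary gaps. The toolkit provides:

- **`dwmkit.matrix_model`** — `Pwm`, `Dwm`, `BackgroundModel`,
  `SiteAlignment`; estimation from aligned sites with Dirichlet pseudocounts
  (the DWM prior is the outer product of marginal columns with total mass
  16), flank extension of site coordinates, reverse complements, information
  content, and the exact independent-columns embedding `dwm_from_pwm`.
- **`dwmkit.scoring`** — log-space likelihood of a window under a Pwm or a
  Dwm (posterior-product approximation with per-position normalisers),
  log-odds against a background, double-stranded window scanning, and
  per-probe total log-odds.
- **`dwmkit.correlation`** — gapped-dinucleotide deviation statistics
  (observed vs. column-independence expectation, 2σ significance, 30%
  abundance filter), per-factor summaries, gap histograms with an
  availability correction, and a multi-factor census.
- **`dwmkit.pipeline`** — the three-branch site-selection rule (log-odds
  > 3.0, else single best ≥ 1.5, else reject), the two-step bootstrap that
  turns a prior PWM plus target sequences into posterior PWM/DWM pairs with
  per-target leave-one-out variants, and benchmark metrics:
  precision/sensitivity curves, midpoint hit rules, discriminative
  precision against decoy sites, and Pearson correlation with per-probe
  binding p-values (geometric-mean combination).
- **`dwmkit.synthetic_data`** — seeded generators for PWM samples,
  correlated sites from PWM mixtures (with closed-form pair joints),
  background sequence, embedded-site benchmark sequences with spacers, and
  probe sets for end-to-end benchmarks.
- **`dwmkit.io` / `dwmkit.cli`** — FASTA, plain-text matrix serialisations,
  BED-like site files, deviation tables, a TAMO-style log-odds dialect
  reader and log-odds↔probability conversion, and a `click` CLI.

Coordinates are 0-based half-open; strands are `+`/`-`; log-odds are in
natural-log units throughout.

## CLI

```sh
dwmkit build sites.txt --pwm-out motif.pwm --dwm-out motif.dwm
dwmkit scan motif.dwm promoters.fa --background auto --out hits.bed
dwmkit correlate sites.txt --factor MCM1 --devs-out devs.tsv --gaps-out gaps.tsv
dwmkit simulate motif.pwm --mode benchmark --n 20 --seed 1 \
    --out bench.fa --truth-out truth.bed
dwmkit benchmark prior.pwm probes.fa annotated.txt --flank 10 --out curves.tsv
```

`dwmkit --config config.yaml <subcommand> ...` reads default option values
per subcommand from a YAML file; `--help` documents every option.

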