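# ripcpe

RIP-Seq binder calling and cytoplasmic polyadenylation element (CPE)
analysis of mRNA 3′-UTRs.

## The problem

RNA immunoprecipitation sequencing (RIP-Seq) identifies the transcripts
bound by an RNA-binding protein by comparing read counts between IP
libraries and control libraries. For CPEB-family proteins, the bound
("binder") transcripts are expected to carry characteristic U-rich
elements in their 3′-UTRs — the consensus CPE (CPEC, `UUUUA(1–2)U`), the
non-consensus CPE (CPENC, `UUUUAAAU`/`UUUUACU`/`UUUUCAU`), the
polyadenylation hexanucleotide (Hex, `AAUAAA`/`AUUAAA`) and the
Pumilio-binding element (PBE, `UGUAAAUA`/`UGUAUAUA`) — and to have longer
3′-UTRs than non-binders.

`ripcpe` implements that analysis as a tested, reusable pipeline for
anyone characterizing an RNA-binding protein's target spectrum:

1. **Binder calling** — per-sample median-of-ratios size factors, a
   per-transcript negative-binomial Wald test of log₂(IP/control) with a
   delta-method standard error, Benjamini–Hochberg FDR adjustment, and the
   binder rule log₂(IP/control) > 0 with q < 0.01 (both configurable).
2. **Motif scanning** — literal, sense-strand scanning of 3′-UTR FASTA for
   the four element classes; per-transcript counts, match positions,
   per-kilobase densities, and BED position tracks with motif clustering.
3. **Binder characterization** — per-class 2×2 contingency of transcripts
   with more than k elements (default k = 3) tested by Fisher's exact
   test; Mann–Whitney rank-sum comparisons of CPEC/CPENC density and UTR
   length; optionally a penalized logistic "binder score" on UTR features.
4. **Synthetic data** — a seeded generator producing NB count matrices
   with planted IP enrichment and UTR sequences with planted element
   densities and length differences, plus ground-truth labels, so the
   entire pipeline is testable without access to raw sequencing data.

The statistical core is the NB model `var = μ + α μ²`: group means on
normalized counts, method-of-moments dispersion with a conservative
moderation floor, Wald statistic `z = log2fc / se(log2fc)` against the
standard normal. See `docs/methods.md` for every modelling choice.

## Worked example

```python
from ripcpe import (GeneratorConfig, generate_utr_set, generate_count_matrix,
                    RIPEnrichment, compare_binders, scan_utrs)
from ripcpe.io import profiles_to_frame

cfg = GeneratorConfig(n_transcripts=2000, seed=7)
utrs, truth = generate_utr_set(cfg)
counts, design = generate_count_matrix(truth, cfg)

res = RIPEnrichment(counts, design).fit()
print(res.summary())
```

```
RIP-Seq NB enrichment (Wald test, BH-adjusted)
===============================================
transcripts:        2000
tested (non-zero):  2000
IP / control reps:  3 / 3
binder rule:        log2fc > 0 and q < 0.01
binders called:     185
median dispersion:  0.08164
median |log2fc|:    0.298
```

185 of the 200 planted binders are recovered at the default thresholds.
Continuing with the motif comparison:

```python
profiles = profiles_to_frame(scan_utrs(utrs))
report = compare_binders(profiles, res.table["is_binder"].to_dict())
c = report.fisher["CPEC"]
print(f"CPEC >3 elements: OR={c.odds_ratio:.2f}, Fisher p={c.fisher_p:.2e}")
r = report.ranksum["utr_length"]
print(f"UTR length medians: binder={r.median_binder:.0f} nt, "
      f"non-binder={r.median_nonbinder:.0f} nt, rank-sum p={r.pvalue:.2e}")
```

```
CPEC >3 elements: OR=3.24, Fisher p=8.01e-13
UTR length medians: binder=1092 nt, non-binder=803 nt, rank-sum p=7.34e-09
```

Called binders are strongly enriched for transcripts with more than three
CPEC elements (odds ratio 3.2) and have markedly longer 3′-UTRs — the
expected signature of a CPEB-bound target set.

The same analysis is available from the shell:

```bash
ripcpe simulate --outdir sim --seed 7
ripcpe call-binders --counts sim/counts.tsv --design sim/design.tsv --out enrichment.tsv
ripcpe scan --fasta sim/utrs.fasta --out scan
ripcpe compare --profiles scan/profiles.tsv --binders enrichment.tsv --out cmp --score
# or everything at once, from a YAML config:
ripcpe run-all --config run.yaml --outdir out --seed 7
```

`run-all` writes the enrichment table, motif profiles, a BED6 motif track,
the comparison report (JSON) and a manifest with checksums; identical
config and seed reproduce every output byte for byte.

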