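# mthaplostat

Population-genetic analysis of mitochondrial haplotypes: haplotype calling
from aligned mtDNA sequences, molecular diversity indices, one-level AMOVA
with permutation testing, pairwise-distance summaries (including Nei's d)
and median-joining haplotype networks — with a synthetic-survey generator
so the whole pipeline runs with no external data.

The package is aimed at conservation and wildlife geneticists working with
maternally inherited markers. It ships the reference data for the African
lion (*Panthera leo*) 12S–16S fragment: a catalog of 17 published
haplotype profiles (H1–H12 and the Zambian Z1–Z5) over 31 polymorphic
columns of a 1882-column alignment, and the sampling design of a
165-individual Zambian survey spanning five areas grouped into an eastern
(LV, CO, ZA) and a western (KF, SI) region.

## The statistics

For haplotype counts n_h (n total, p_h = n_h/n):

- **gene diversity** — the probability that two individuals sampled
  without replacement carry different haplotypes, estimated unbiasedly as
  h = n(1 − Σp²)/(n − 1), with sampling variance
  V = 2/(n(n−1)) · {2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²};
- **AMOVA / Fst** — pairwise inter-individual distances (haplotype
  identity or per-column profile differences) partitioned into
  among-population (Va) and within-population (Vb) variance components;
  Fst = Va/(Va + Vb), tested by permuting individuals among populations;
- **π and Nei's d** — mean pairwise differences within and between
  populations, with d = π_XY − (π_X + π_Y)/2;
- **median-joining network** — minimum-spanning networks over haplotype
  profiles under Hamming distance, augmented with majority-consensus
  median (Steiner) vectors.

See `docs/methods.md` for formulas, conventions and tie-breaking rules.

## Worked example

```python
from collections import Counter
import mthaplostat as mh

design = mh.load_default_design()          # the 165-sample survey design
aln, meta, _ = mh.generate_study(design, seed=1)

catalog = mh.load_reference_catalog()      # 17 haplotypes, 31 columns
assignments, updated = mh.call_haplotypes(aln, catalog)
counts = Counter(a.haplotype for a in assignments)

res = mh.gene_diversity(counts)
print(f"gene diversity h = {res.h:.4f} +/- {res.sd:.4f} (n = {res.n})")

hap_of = {a.sample_id: a.haplotype for a in assignments}
region = meta.group_of("region")
members = [hap_of[s] for s in meta.sample_ids]
labels = [region[s] for s in meta.sample_ids]
identity = mh.pairwise_difference_matrix(updated, "identity")
am = mh.amova_one_level(members, labels, identity)
p = mh.permutation_test(am, members, labels, identity,
                        permutations=1000, seed=1)
print(f"AMOVA east vs west: Fst = {am.fst:.5f} "
      f"({am.percent_among:.2f}% among, {am.percent_within:.2f}% within), "
      f"p = {p:.4g}")
```

prints

```
gene diversity h = 0.7319 +/- 0.0174 (n = 165)
AMOVA east vs west: Fst = 0.47499 (47.50% among, 52.50% within), p = 0.000999
```

Countrywide diversity is high (h ≈ 0.73: two random individuals usually
differ in haplotype), yet nearly half of the molecular variance lies
*between* the eastern and western regions — an Fst of 0.475 (p < 0.001
by 1000 permutations) indicating strong matrilineal differentiation and
little female-mediated gene flow between the regions.

The same analysis is available from the shell:

```sh
mthaplostat simulate --seed 1 --outdir sim/
mthaplostat run --fasta sim/alignment.fasta --metadata sim/metadata.tsv \
                --catalog sim/catalog.tsv --outdir out/ --seed 1
```

which writes per-sample assignments, frequency/diversity tables, AMOVA
tables (TSV + JSON), within/between distance summaries, the
median-joining network edge list and a checksummed manifest.

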