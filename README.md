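# cas9rvl

In vitro Cas9 cleavage-specificity analysis from doped random-variant target
libraries.

## The problem

To map how sequence variation affects *S. pyogenes* Cas9 cleavage, one can
challenge a *random variant library* (RVL) — thousands of plasmid targets
synthesized around one canonical protospacer+PAM with a controlled
per-position variant rate — with a Cas9::gRNA complex in vitro, then compare
deep-sequencing counts of the surviving (uncut) pool against the untreated
pool. Species that Cas9 cleaves well are depleted; species it tolerates are
not. `cas9rvl` implements that analysis end to end for experimentalists and
computational biologists working with such depletion assays, together with a
fully specified simulator that generates realistic libraries and cleavage
time courses with known ground truth.

## The model

The 35 nt variable insert is indexed −5..29: positions −5..0 and 24..29 are
fully random 6 nt flanks, 1..20 the protospacer (position 1 PAM-distal,
11–20 the seed region), and 21..23 the PAM (NGG; the N at 21 is fully
random). The 22 *doped* positions (1–20, 22–23) carry the canonical base
with probability 1 − r and each alternative with r/3 (default r = 0.10).

For each species X and sample,

```
Representation_X = [reads of X] / [reads of the reference population]
Retention[X]     = log2( Representation_X[cleaved] / Representation_X[uncleaved] )
```

where the reference population is either the aggregate of species with 4–7
mismatches to the canonical target or a spike-in of an unrelated target
library — both essentially uncleavable, so Retention ≈ 0 means "not cut" and
more negative means more cleavage. Only species with ≥ 50 reads in the
uncleaved sample are analyzed.

Aggregated views:

* **single-variant grid** — per (position, base): the median retention over
  species carrying exactly that one doped-region variant (flanks free), or,
  for flank/PAM-N positions, over perfect-target species with that base;
* **heat map** — (median variant retention)/(median WT retention): ≈1
  WT-like, ≈0 uncleaved, >1 depleted faster than WT;
* **double-variant matrix** — a symmetric 92×92 grid (positions 1–23 × 4
  bases) of median log retentions LR, singles on the diagonal, with the
  synergy statistic `(LR_M12/LR_WT) / [(LR_M1/LR_WT)·(LR_M2/LR_WT)]`
  (1 ⇔ multiplicative rate effects);
* **time courses** — median retention vs time per variant category with
  across-species SD.

The simulator assigns each species a cleavage weight w (product of
per-mismatch penalty multipliers) and evolves survival with biphasic
kinetics `s(w,t) = f·e^(−k_fast·w·t) + (1−f)·e^(−k_slow·w·t)`, then draws
multinomial reads per sample (or exact expectations in noise-free mode).

## Worked example

```python
import cas9rvl as c
from cas9rvl.config import AnalysisBlock

cfg = c.RunConfig()                      # demo guide, 10% doping, biphasic kinetics
cfg.simulation.n_species = 2000
cfg.simulation.depth = 2_000_000
sim = c.run_simulation(cfg, seed=1)
table = sim.result.counts
print("library complexity (>=50 reads uncut):", c.library_complexity(table, "uncut"))
res = c.analyze_counts(table, sim.spec, AnalysisBlock())
print(f"WT median retention at t=180 min: {res.singles.wt_median:.2f} (n={res.singles.wt_n})")
for el in [(16, "T"), (20, "A"), (22, "T"), (10, "G")]:
    cell = res.singles.cell(*el)
    print(f"variant {el[0]}{el[1]}: median retention {cell['median']:.2f}, "
          f"ratio to WT {res.heat.loc[el]:.2f}")
```

prints

```
library complexity (>=50 reads uncut): 2040
WT median retention at t=180 min: -2.92 (n=193)
variant 16T: median retention -0.47, ratio to WT 0.16
variant 20A: median retention -1.89, ratio to WT 0.65
variant 22T: median retention -0.07, ratio to WT 0.02
variant 10G: median retention -3.65, ratio to WT 1.25
```

Read: perfect targets are strongly depleted (−2.92); a seed transversion at
position 16 nearly abolishes cleavage (ratio 0.16), a PAM-proximal variant
at position 20 is well tolerated (0.65), a PAM transversion is essentially
uncleaved (0.02), and a central position-10 variant is depleted *faster*
than WT (1.25).

The same pipeline runs from the shell:

```
cas9rvl run-all --config demo.yaml --seed 1 --out results/
cas9rvl simulate --out sim/ --fastq        # emit per-sample FASTQ
cas9rvl count sim/uncut.fastq sim/cut_t180.fastq --out counts.tsv
cas9rvl score --counts counts.tsv --out retention.tsv
cas9rvl aggregate --counts counts.tsv --out grids/
```

All outputs are plain TSV/JSON and byte-identical for a fixed config + seed.

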