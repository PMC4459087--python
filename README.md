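# satclock

**Substitution saturation and node-age-dependent bias in fossil-calibrated
molecular divergence dating.**

Molecular clocks date the tree of life by dividing genetic distance by a
rate inferred from fossil-calibrated nodes. When sequences are saturated —
repeated substitutions at the same sites erase earlier changes — observed
distance is no longer proportional to time, and the calibrated rate becomes
an *apparent* rate specific to the calibration's depth. `satclock` packages
this mechanism for phylogeneticists who want to probe it quantitatively:

* a closed-form **saturation model**: percent distance grows at a background
  rate *r* up to an onset *T₀*, then each successive window of width *w*
  keeps only a fraction *f* of the previous slope (defaults r = 1 %/MY,
  T₀ = 20 MY, f = 0.5, w = 10 MY);
* strict-clock **bias mechanics**: a single calibration of true age *a*
  implies rate d(a)/a, so estimated ages are d(t)·a/d(a); multiple
  calibrations pool through-origin, Σ aᵢd(aᵢ)/Σ aᵢ²;
* a **synthetic data generator**: a 17-taxon aquatic-bird chronogram
  (youngest split 0.5 MY, crown flamingos 4.4 MY, penguin–tubenose split
  62 MY), seven slow nuclear loci plus one fast mitochondrial partition
  evolved under a Kimura two-parameter clock, and a table of seven vetted
  fossil minima (8.7, 23.0, 28.3, 32.6, 33.0, 51.8, 60.5 MY);
* a distance-based **dating engine** with minimum-age calibrations,
  point-minimum or soft (prior-shaped) rate fitting, column-bootstrap CIs
  and a fossil-record consistency check;
* a 45-run **sensitivity harness** sweeping locus, taxon and calibration
  subsets, with per-node deviation classes and factor summaries.

## Worked example

```python
import satclock as sc

tree = sc.make_reference_chronogram(0)            # 17 taxa, root 64 MY
dist = sc.simulate_stylized_distances(tree)       # exact saturated distances

# calibrate with only the two youngest constraints (8.7 and 32.6 MY)
young = sc.date_tree(tree, dist, sc.YOUNGEST_TWO, bootstrap_reps=0)
print(round(young.rate, 4))                       # 0.801  (true rate: 1 %/MY)
old = young.by_label()["divergence_Sphenisciformes_Procellariiformes"]
print(round(old.point_age, 2))                    # 36.75  (true age: 62 MY)

for v in sc.check_fossil_consistency(young.estimates, sc.DEFAULT_CALIBRATIONS, tree):
    print(v.label, v.min_age, round(v.point_age, 2))
# stem_Sulidae 33.0 32.15
# stem_Fregatidae 51.8 36.03
# divergence_Sphenisciformes_Procellariiformes 60.5 36.75

# with all six standard constraints the fossil record is satisfied, but the
# young crown flamingo node (true age 4.4 MY) is overestimated:
full = sc.date_tree(tree, dist, sc.STANDARD_SIX, bootstrap_reps=0)
print(sc.check_fossil_consistency(full.estimates, sc.DEFAULT_CALIBRATIONS, tree))  # []
print(round(full.by_label()["crown_Phoenicopteridae"].point_age, 2))               # 7.21
```

Reading: shallow calibrations recover the true rate but compress saturated
deep nodes far enough to *reject* three well-supported fossil minima; using
all six constraints restores consistency with the fossil record at the cost
of dating the young flamingo radiation ~64 % too old. That asymmetry — young
nodes inflated whenever deep calibrations dominate — is the package's core
phenomenon.

The same story can be run from the shell:

```sh
satclock simulate --seed 0 --out fixtures/
satclock date --tree fixtures/chronogram.nwk --calibrations fixtures/calibrations.tsv \
    --alignments fixtures/NFKBIZ_intron6.fasta --bootstrap 100 --out dated/
satclock sweep --seed 0 --out sweep/ --plot
satclock bias-profile --out bias.tsv
satclock report --seed 0 --out report.md
```

The numbered drivers under `analysis/` reproduce the full study arc
(fixtures → closed-form bias profile → parameter recovery → fossil
consistency → 45-run sweep) and write their tables under `results/`.

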