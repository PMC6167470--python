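# gcbrainbow

Stochastic simulation of germinal-center (GC) reactions with
brainbow/confetti-style multi-color staining, and analytics that quantify
how well the *observable* color pattern of a GC reports on its *hidden*
clonal and lineage structure.

## The scientific problem

Germinal centers are the microanatomical sites where B cells mutate their
antibody genes and compete for antigen-specific survival signals, producing
affinity-matured antibodies. A central question is how oligoclonal a GC
becomes: does one B-cell clone (or one lineage of a clone) take over, and
how fast? Multi-color fate-mapping ("brainbow"/"confetti") mice address
this experimentally: a tamoxifen pulse stochastically and heritably labels
B cells with one of up to ten colors, so a GC swept by a single lineage
tends to turn single-colored. But the mapping from color dominance to
clonal dominance is lossy — two clones can share a color, many cells stay
unstained, and staining happens at one moment while clonal competition is a
movie. Interpreting color data therefore needs a forward model: simulate
GCs with known clonal structure, stain them in silico exactly as the
experiment would, and measure how well color statistics recover the truth
under different staining designs.

`gcbrainbow` implements that forward model as a non-spatial, two-compartment
(dark zone / light zone) stochastic birth–death simulation of single B
cells, with:

* a low-dimensional integer **shape space** with Gaussian affinity and
  ±1-step somatic hypermutation;
* **GC dynamics**: founder influx, dark-zone division bursts, light-zone
  selection through limited T-follicular-helper capacity, recycling,
  dynamic numbers of divisions, antigen consumption;
* **staining protocols**: pre-reaction founder staining, one-shot staining,
  and tamoxifen-like decaying staining with exact calibration of the
  realized stained fraction, using measured confetti color-probability
  tables (4-color, 10-color, 10-color founder) plus an idealized
  equiprobable palette;
* **lineage tracking** that distinguishes *clones* (descendants of one
  founder) from *lineages* (descendants of one cell alive at the staining
  time), with optional full genealogies and Newick export;
* **dominance metrics**: clonal dominance F, lineage dominance L, color
  dominance C, color density D and their product PDD (the in-silico analog
  of the normalized color dominance density score used on imaging data);
* **cohort analytics**: Pearson correlations with Fisher confidence
  intervals, sweeps over staining day / stained fraction / threshold /
  color scheme, kept-vs-deleted threshold analyses, dominant-color
  switching.

See `docs/methods.md` for model assumptions, every parameter with units and
rationale, and limitations.

## Worked example

Simulate a small cohort with day-2 tamoxifen staining, and correlate
lineage dominance with the color-dominance-density score PDD at day 11
post staining, with and without a 40 % staining threshold:

```python
from gcbrainbow import SimConfig, StainingProtocol, get_scheme
from gcbrainbow.analysis import correlate_dominance, run_cohort

config = SimConfig()
protocol = StainingProtocol(
    mode="decay", scheme=get_scheme("tamoxifen"), t_start=48.0
)
t_eval = 48.0 + 11 * 24.0  # day 11 post tamoxifen

cohort = run_cohort(config, protocol, n_gc=50, base_seed=7,
                    record_times=[t_eval])
for T in (0.0, 0.40):
    res = correlate_dominance(cohort, "L", "PDD", T, t_eval)
    print(f"T={T:.2f}  r(L, PDD)={res.r:.3f}  "
          f"95% CI=({res.ci_low:.3f}, {res.ci_high:.3f})  n={res.n}")
```

Output:

```
T=0.00  r(L, PDD)=-0.064  95% CI=(-0.336, 0.218)  n=50
T=0.40  r(L, PDD)=0.583  95% CI=(0.275, 0.782)  n=29
```

Unfiltered, the color score is uninformative — GCs with many unstained
cells drag the correlation to zero; keeping only GCs stained above 40 %
recovers a strong correlation, which is exactly the staining-threshold
design conclusion the package is built to probe.

The same analyses are available from the command line:

```
$ gcbrainbow sweep-threshold --n-gc 50 --seed 7 --out /tmp/demo
 threshold         r    ci_low  ci_high  n
       0.0 -0.064080 -0.336427 0.218159 50
       0.1  0.115573 -0.184210 0.395684 45
       0.2  0.293458 -0.011499 0.548471 42
       0.3  0.303998 -0.008297 0.562262 40
       0.4  0.582566  0.274715 0.782085 29
       0.5  0.558663  0.167330 0.797918 21
```

Every command writes tidy CSV tables plus a JSON manifest (package version,
full configuration, seeds, output checksums), so any table can be
regenerated bit-for-bit.

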