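# cladistron

Morphological cladistics for mixed binary / ordered / unordered character
matrices, built around the workflow used in beaked-whale (Ziphiidae)
systematics: parsimony tree search under equal and implied weighting,
resampling ("GC") node support, strict consensus, selection of a working
cladogram across concavity constants, stratigraphic calibration of the
chosen tree from fossil tip ranges and node constraints, and parsimony /
squared-change mapping of biogeographic areas and body-size proxies.

It is aimed at palaeontologists and systematists who analyse discrete
morphological matrices (a few dozen taxa, tens of characters, heavy missing
data) and want a scriptable, fully reproducible version of the classic
PAUP*/TNT/Mesquite tool chain, plus a simulator for testing the whole
pipeline against data with known history.

## The quantities it computes

For a character *i* on a tree, let *s<sub>i</sub>* be its parsimony steps
(Fitch counts for unordered characters; ordered characters cost |state
difference| per change), *m<sub>i</sub>* the minimum steps over all trees and
*g<sub>i</sub>* the steps on the star tree. Then

* tree length `S = Σ s_i`, extra steps `es_i = s_i − m_i`;
* implied-weighting fit of a tree at concavity `K`:
  `F = −Σ K/(K + es_i)` (reported with the conventional negative sign, so a
  homoplasy-free matrix scores −n_chars and, at fixed K, better trees are
  more negative); searches under implied weighting minimise the equivalent
  distortion `Σ es_i/(K + es_i)` with exact rational tie-breaking;
* ensemble consistency index `CI = Σm_i / Σs_i` and retention index
  `RI = (Σg_i − Σs_i) / (Σg_i − Σm_i)` (RI over parsimony-informative
  characters; both conventions are reported);
* GC support of a group = % of resampling replicates recovering it − % of
  its best-supported incompatible rival, in [−100, 100].

Searches are exact (exhaustive or branch-and-bound with an admissible
per-character completion bound) up to moderate sizes and heuristic
(random-addition + NNI/SPR/TBR with an equal-score closure sweep) beyond;
equally optimal trees are condensed by the zero-minimum-branch-length
collapse rule (the convention published MPC counts depend on — both rules
ship).

## Worked example

```python
import cladistron as cl

tree = cl.simulate_tree(10, seed=1)                      # known history
sim = cl.simulate_matrix(tree, cl.SimConfig(
    n_taxa=10, n_binary=14, n_ordered=6, n_unordered=2,
    rate=0.08, missing_fraction=0.10, seed=1))

res = cl.branch_and_bound(sim.matrix, cl.SearchConfig(criterion="implied", k=3.0))
print(res.n_mpcs)                                        # 9
s = res.best_score
print(f"length={s.length} fit={s.fit:.2f} ci={s.ci:.2f} ri={s.ri:.2f}")
# length=24 fit=-20.75 ci=0.79 ri=0.71

sup = cl.resample_support(sim.matrix, replicates=200, seed=7)
for row in sup.rows()[:3]:
    print(f"{row['group']}: freq {row['frequency']:.1f}  GC {row['gc']:.1f}")
# t04+t05: freq 95.5  GC 94.0
# t02+t03+t04+t05+t06+t07+t08+t09: freq 79.5  GC 79.5
# t03+t08: freq 72.0  GC 72.0
```

Reading: implied weighting at K = 3 finds nine equally optimal cladograms of
length 24; the fit −20.75 against 22 characters says most characters are
nearly homoplasy-free (CI 0.79), and the `t04+t05` pair is recovered in
95.5% of symmetric-resampling replicates with almost no contradicting
signal.

The same operations are available from the shell:

```bash
cladistron simulate --taxa 34 --chars 28,19,4 --rate 0.05 --seed 42 --out sim.nex
cladistron matrix summarize sim.nex
cladistron search --matrix sim.nex --criterion implied --k 3 --mode heuristic --seed 1
cladistron calibrate --tree tree.nwk --nodes nodes.tsv --tips tips.tsv --out timetree.nwk
cladistron run --config study.yaml      # full pipeline, report.json + artifacts
```

Bundled under `cladistron.data` are the printed skull-measurement tables
(for the morphometric-ratio utilities and the `verify_ratios` report), the
node-calibration and tip-range tables (Ma), the four-area biogeographic
coding, and a clearly-labelled *synthetic* stand-in working tree so that
calibration and trait mapping are runnable end-to-end out of the box.

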