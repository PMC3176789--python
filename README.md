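# symmotif

Symmetry-aware motif discovery on simulated transcription-factor binding
sites.

Many transcription factors bind DNA as homodimers, and their binding motifs
are reverse-complement symmetric (or nearly so). A motif discovery method
that is free to use each binding site in either orientation will almost
always find an *asymmetric* motif with higher information content than the
true symmetric one — an overfitting artifact, not a discovery. `symmotif`
is a simulation laboratory for this problem: because every dataset is
generated from a known energy model, the accuracy of each modeling
assumption can be measured exactly, and the package shows how a properly
corrected E-value recovers the correct symmetry class even when raw
information content points the wrong way.

## The model

A binding site of length L has additive energy
`E(s) = sum_j epsilon(s_j, j)` (kT units, consensus = 0), and is occupied
by the factor with the Fermi–Dirac probability

    theta(E) = 1 / (1 + exp(E - mu)),

where `mu` is the chemical potential (default −0.5, so the consensus is
bound with probability 0.38). Sites are sampled i.i.d. from the normalized
occupancy distribution over all 4^L sequences. Eight true models ship with
the package (`M7A-1/2`, `M7S-1/2`, `M6A-1/2`, `M6S-1/2`): 7-long motifs with
an asymmetric consensus GTGGACC or its odd-symmetric position-swapped twin
GTGGCAC (center position unconstrained, consensus GTGSCAC counting both
strands), and 6-long center-deleted versions GTGACC (asymmetric) and GTGCAC
(fully symmetric).

Motifs are estimated three ways: `fixed` (sites as given — the control),
`asymmetric` (each site in the orientation that maximizes information
content, exhaustively for ≤ 12 sites, by seeded multi-restart coordinate
ascent otherwise), and `symmetric` (every site counted in both
orientations, doubling the effective sample and forcing exact
reverse-complement symmetry).

Model selection uses `-ln(E-value)`: the tail p-value of the observed
information content under the background null (computed exactly by a
log-space dynamic program over column count distributions), multiplied by
the number of possible alignments — 2^N for the orientation-free search
versus one for the symmetric fit. Accuracy is the squared Pearson
correlation (R²) between true and predicted log binding probability
(both strands summed) over the complete 4^L sequence landscape.

## Worked example

```python
import symmotif as sm

truth = sm.default_matrix("M7S-1")          # odd-symmetric, consensus GTGGCAC
sample = sm.simulate(truth, n_sites=500, seed=17)

cfg = sm.DiscoveryConfig(seed=17)
asym = sm.discover_asymmetric(sample, cfg)  # orientation-free search
sym = sm.discover_symmetric(sample, cfg)    # both orientations combined

rep_a, rep_s = sm.evalue_report(asym), sm.evalue_report(sym)
choice = sm.select_model(rep_a, rep_s)

print(f"true motif information: {sm.enumerate_landscape(truth).information():.2f} bits")
print(f"asymmetric fit: I = {rep_a.information_bits:.2f} bits, -lnE = {rep_a.minus_ln_evalue:.0f}")
print(f"symmetric  fit: I = {rep_s.information_bits:.2f} bits, -lnE = {rep_s.minus_ln_evalue:.0f}")
print(f"selected model: {choice.verdict} (margin {choice.margin:.0f})")
for label, model in [("asymmetric", asym), ("symmetric", sym)]:
    r2 = sm.evaluate_model(truth, model).r_squared
    print(f"landscape R^2 ({label} fit): {r2:.3f}")
```

which prints:

```
true motif information: 2.92 bits
asymmetric fit: I = 4.11 bits, -lnE = 1019
symmetric  fit: I = 3.10 bits, -lnE = 1043
selected model: symmetric (margin 24)
landscape R^2 (asymmetric fit): 0.990
landscape R^2 (symmetric fit): 0.994
```

The orientation-free search reports a full bit more information than the
truth contains — the overfitting artifact — yet the E-value ranking still
selects the symmetric model, which also predicts the binding landscape
better. On asymmetric data the same comparison favors the asymmetric model
by a wide margin, and a symmetric fit there costs roughly half the
explained variance (R² drops from ~0.95 to ~0.2–0.4).

The same pipeline is scriptable from a shell:

```
symmotif simulate --model M7S-1 --n 500 --seed 17 --out run/
symmotif significance --sites run/M7S-1_sample.tsv --out run/report.json
symmotif replicate --out study/            # all eight models, full report
symmotif hincii-demo                       # the classic restriction-enzyme example
```

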