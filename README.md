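# piezoflux

Tools for quantifying the conformational state of the trimeric
mechanosensitive channel PIEZO1 from 3D-MINFLUX/DNA-PAINT localization
microscopy, together with the standard functional-assay readouts
(patch-clamp and calcium imaging) and docking-pose contact statistics used
to characterize PIEZO1 variants and their response to chemical agonists
such as Yoda1/Yoda2.

## Who this is for

Labs doing single-molecule localization microscopy of multimeric membrane
proteins who need a tested, scriptable version of the MINFLUX
post-processing chain — and anyone who wants the accompanying
electrophysiology / calcium-imaging fits in one reproducible package
instead of per-lab spreadsheet macros.

## The core computation

PIEZO1 is a propeller-shaped trimer whose three blades flatten when the
channel is activated. With an ALFA tag at the distal end of each blade and
DNA-PAINT imaging, the *interblade distance* — the mean of the three
pairwise distances between the blade-tip label positions —

```
d_interblade = (d12 + d13 + d23) / 3
```

is a direct readout of flattening (curved ≈ small, flat ≈ large). The
pipeline that produces it from a raw localization table is:

1. **Quality filter** — keep localizations with cfr ≤ 0.8 and efo below a
   cutoff (default: the dataset's 95th percentile) to reject multi-emitter
   events.
2. **Trace grouping** — localizations sharing a trace ID (one DNA-PAINT
   binding event) form a trace; traces with < 3 localizations or a sample
   SD > 10 nm on any axis are dropped; the first 2 localizations of each
   trace are trimmed.
3. **z correction** — z × 0.7 for the coverslip/sample refractive-index
   mismatch; then each trace is reduced to its center of mass.
4. **Protomer merging** — DBSCAN (minPoints 2, ε 8 nm) merges repeated
   detections of the same blade tip into a protomer site.
5. **Trimer rules** — a site triple is a triple-labelled trimer iff all
   pairwise distances < 40 nm (the physical bound for a fully flattened
   channel), no other site lies within 60 nm of any member, and the
   maximum internal angle is < 120°.

Condition cohorts are compared with a normality-gated procedure
(D'Agostino–Pearson gate → Student's t-test or Mann–Whitney U).

The functional modules implement: mechanical threshold (first stimulus
exceeding 6 baseline SDs), inactivation kinetics
`C1 + C2·exp(−(t−t0)/τ_inact)`, Boltzmann pressure-response
`I/I_max = I_max_norm / (1 + exp((P−P50)/k))`, peak/sustained ratio,
single-channel amplitude (two-Gaussian mixture of the trace histogram) with
I/V-regression conductance, F/F0 calcium time courses and four-parameter
logistic EC50 fits, plus per-residue ligand-contact frequencies (fraction
of docking poses with any atom within 3.5 Å) across a pose ensemble.

A first-class synthetic-data generator (`piezoflux.synthgen`) produces
ground-truth-annotated inputs for every stage, so the whole chain is
testable without any microscope export.

## Worked example

```bash
python examples/01_minflux_interblade_pipeline.py
```

```
CTL: 9384 localizations -> 1053 trace centers -> 404 protomer sites -> 98 trimers; interblade 22.36 +- 0.55 nm (SD 5.49)
Yoda1: 10600 localizations -> 1188 trace centers -> 411 protomer sites -> 109 trimers; interblade 23.90 +- 0.46 nm (SD 4.84)

student-t: p = 3.23e-02, mean shift = 1.55 nm
```

Two synthetic conditions (curved population, mean 21.7 nm; partially
flattened, 23.9 nm) are pushed through the full pipeline; roughly a hundred
triple-labelled trimers survive the geometric rules per condition, and the
gated test detects the flattening shift. `examples/02–04` do the same for
the patch-clamp fits, the calcium dose-response and the pose-contact
profile.

The same operations are available from the shell:

```bash
piezoflux simulate minflux --out sim --seed 5
piezoflux filter sim/localizations.csv --out filt
piezoflux trimers filt/trace_centers.csv --out tri
piezoflux compare tri_ctl/trimers.csv tri_yoda/trimers.csv
```

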