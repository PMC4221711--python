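# tracefate

Analysis pipeline for studies of metabolic rewiring during the
epithelial–mesenchymal transition (EMT) in cancer cell lines: ¹³C
isotope-tracing statistics, cross-cell-line differential screens, and a
survival meta-analysis — each paired with a synthetic-data generator that
carries known ground truth, so every estimator in the pipeline can be
validated end to end.

## The scientific problem

Cells that undergo EMT often become drug resistant and reroute their
central carbon metabolism. Four computational readouts diagnose this
rewiring:

1. **Glycolysis/OXPHOS ratio** — per-well PPR/OCR (proton production over
   oxygen consumption) from extracellular-flux measurements, compared
   between parental and mesenchymal cells with a Student t-test.
2. **Mass-isotopologue distributions (MIDs)** — under a U-¹³C₆ glucose
   tracer, the M+2 fraction of glutamate (and of citrate, α-ketoglutarate,
   malate) measures glucose carbon entering the TCA cycle through pyruvate
   dehydrogenase (PDH); under U-¹³C₅ glutamine, the M+5 glutamate fraction
   measures glutaminolysis. Raw intensities are first corrected for
   natural ¹³C abundance (p ≈ 1.07 % per carbon) by solving `C·x = y`
   under `x ≥ 0` (NNLS), where `C` is the closed-form binomial smearing
   matrix `C[i,j] = C(N−j, i−j) p^(i−j) (1−p)^(N−i)`.
   The ratio (glutamate M+2)/(pyruvate M+3) is a PDH-activity proxy equal
   to `g_pdh · (1 − q_gln)` in the first-turn labelling model, which makes
   the model parameters recoverable from paired tracer arms.
3. **Consistency screens** — a metabolite (or gene) is a hit only if it
   changes with |FC| > 2 and p < 0.05 (genes: |FC| > 5 and BH-FDR
   < 10⁻⁵) *in every one of three cell-line models, in the same
   direction*. The intersection-across-models rule is what drives the
   false-positive rate to near zero.
4. **Survival meta-analysis** — per cohort, patients are median-split on
   expression of a gene of interest (e.g. *PDK4*), the low-vs-high hazard
   ratio is estimated by Cox partial likelihood (Newton's method, Efron
   ties), and per-cohort log-HRs are combined by fixed-effect
   inverse-variance weighting: `θ̂ = Σwᵢθᵢ/Σwᵢ`, `w = 1/se²`,
   `se = (Σw)^(−1/2)`.

## Worked example

```python
from tracefate import FluxParams, recover_flux_params, MID, COMPOUNDS
from tracefate.simulate import simulate_tracer_labeling
from tracefate.pipeline import analyze_tracer_table
import numpy as np

truth = FluxParams(f_pyr=0.8, g_pdh=0.6, q_gln=0.5, noise_cv=0.05)
glc = simulate_tracer_labeling(truth, "glucose", "mes", 5, seed=1)
gln = simulate_tracer_labeling(truth, "glutamine", "mes", 5, seed=2)
stats_glc, mids_glc = analyze_tracer_table(glc)
stats_gln, mids_gln = analyze_tracer_table(gln)

def mean_mid(mids, compound):
    v = np.mean([m.fractions for (c, _), m in mids.items() if c == compound], axis=0)
    return MID(COMPOUNDS[compound], v / v.sum())

rec = recover_flux_params(mean_mid(mids_glc, "pyruvate"),
                          mean_mid(mids_glc, "glutamate"),
                          mean_mid(mids_gln, "glutamate"))
print(f"g_pdh={rec.g_pdh:.3f} f_pyr={rec.f_pyr:.3f} q_gln={rec.q_gln:.3f}")
```

prints

```
g_pdh=0.605 f_pyr=0.795 q_gln=0.500
```

i.e. the three flux fractions planted in the generator (0.6, 0.8, 0.5)
are recovered to within the measurement noise from 5 noisy replicates.

The full demo loop (every stage on synthetic inputs, one root seed):

```bash
tracefate run-all --seed 1 --out demo_out
```

writes corrected MID statistics, the Seahorse comparison, flux recovery,
metabolite/gene hit lists, the isoform report, a forest-plot CSV and a
run manifest. With the default presets the mesenchymal condition shows
higher glutamate M+2 and a lower PPR/OCR than the parental condition, and
*PDK4* (planted 8-fold down) is the only PDK isoform flagged. Individual
stages are available as `tracefate simulate|mida|screen-metabolites|
screen-genes|survival`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch at the given seed (outputs
under `scratch/`) and writes the results JSON.
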