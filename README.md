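# tractnet

Structural brain-network (connectome) analysis for diffusion-MRI tractography
studies, aimed at researchers comparing network efficiency between clinical
groups — the motivating use case is Parkinson's disease (PD) patients versus
healthy controls (HC), with network measures related to the UPDRS part-3
motor score.

The pipeline takes, per subject, a parcellation label volume (NIfTI), a
fractional-anisotropy (FA) map (NIfTI), and a whole-brain streamline set
(TRK/TCK), and produces:

1. **Parcellation handling** — restriction to an 85-ROI analysis set
   (Desikan–Killiany cortex plus bilateral subcortical structures and
   brainstem), and splitting of each putamen into anterior/posterior parts
   at the vertical plane through the anterior commissure, giving 87 network
   nodes (87 × 86 = 7,482 directed connection slots).
2. **Connectivity matrices** — 87 × 87 symmetric matrices weighted by mean
   FA, by number of streamlines (NOS), and binarized; a streamline connects
   the two ROIs containing its endpoints. Connections found in fewer than
   50% of subjects are discarded (group-consensus threshold), and FA/NOS
   weights are divided by their cohort-wide maxima so weights lie in [0, 1].
3. **Efficiency** — nodal and whole-brain global efficiency
   `E_glob(i) = (1/(n−1)) Σ_{j≠i} 1/d(i,j)` with shortest-path distances
   `d` on inverse-weight lengths, and local efficiency
   `E_loc(i) = Σ_{j≠h∈N(i)} (w_ij w_ih / d_jh(N(i)))^{1/3} / (k_i(k_i−1))`
   (binary form without the cube root). Whole-brain values are the means of
   the nodal vectors.
4. **Statistics** — pooled-variance Student t-tests (PD vs HC), Pearson
   correlation with UPDRS within the PD group, at whole-brain and nodal
   levels, with Benjamini–Hochberg FDR 0.05 applied per measure-and-weighting
   family of nodal tests.

A synthetic phantom-cohort generator produces parcellations, FA maps and
tractograms with a configurable, exactly calibrated correlation between
UPDRS and designated edge weights, so the whole pipeline is testable without
any imaging data.

## Worked example

Generate a 29-subject phantom cohort (14 PD, 15 HC) with a −0.7
UPDRS–weight correlation injected on the edges incident to nodes 1–4, run
the full pipeline, and test for the association:

```python
import numpy as np
import tractnet as tn
from tractnet.core import Weighting

cfg = tn.CohortConfig(
    n_pd=14, n_hc=15, n_rois=10, grid_shape=(16, 16, 16),
    edge_density=0.3, streamlines_per_edge=3,
    effect_r=-0.7,
    affected_edges=[(a, b) for a in range(1, 5) for b in range(a + 1, 11)],
    seed=42,
)
subjects = tn.make_synthetic_cohort(cfg)
node_names = sorted(subjects[0].label_volume.labels.values())
study = tn.build_cohort_study(subjects, node_names, fraction=0.5)
effs = {s.subject_id: {Weighting.FA: tn.summarize(study.matrices[s.subject_id][Weighting.FA])}
        for s in subjects}
results = tn.run_analysis(study, effs, tn.AnalysisConfig(weightings=(Weighting.FA,)))
```

Output (printing the whole-brain rows):

```
FA normalization constant: 0.684
whole-brain E_glob  PD 0.668 (0.039)  HC 0.656 (0.012)
Eglob: group t = +1.10 (p = 0.28); UPDRS r = -0.97 (p = 0.0000)
Eloc: group t = +1.34 (p = 0.19); UPDRS r = -0.97 (p = 0.0000)
```

Reading: the cohort FA maximum was 0.684, so all FA weights were divided by
it; the PD and HC groups do not differ in whole-brain global efficiency
(t-test p = 0.28), but within the patients, efficiency falls steeply as the
motor score worsens (r = −0.97). The whole-brain correlation is stronger
than the per-edge −0.7 because averaging over many affected edges cancels
the independent edge noise. The nodal FDR then flags the nodes carrying the
affected connections.

The same stages are available from a shell:

```sh
tractnet simulate --config cohort.yaml --out data/
tractnet build --subjects data/cohort.tsv --out study/
tractnet metrics --study study/ --out metrics.tsv
tractnet analyze --study study/ --metrics metrics.tsv --out results/
tractnet split-putamen --labels l.nii.gz --table l.tsv --xfm xfm.tsv \
    --region Left-Putamen --out split.nii.gz
```

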