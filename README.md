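# semnf — semantic fMRI neurofeedback engine

`semnf` implements the analysis core of *semantic* fMRI neurofeedback: a
closed-loop paradigm in which participants see not just how strongly an
emotion-related brain region is active, but *which* mental state their
current multi-voxel activity pattern resembles. It is written for
researchers prototyping representational-similarity-based neurofeedback
pipelines and for anyone who wants a fully simulated, deterministic
closed-loop testbed with no scanner data.

## The method

1. **Localizer → RDM.** A preparatory run evokes one multi-voxel anchor
   pattern per mental state (e.g. 'happy', 'content', 'angry', 'sad').
   Pairwise dissimilarities — by default the correlation distance
   *d* = 1 − *r* (Pearson), with Euclidean and shrinkage-regularized
   Mahalanobis alternatives — fill a representational dissimilarity matrix
   (RDM): *d* = 0 for identical patterns, 1 for uncorrelated, 2 for
   anticorrelated.
2. **RDM → semantic map.** Classical (Torgerson) MDS embeds the RDM in 2-D
   or 3-D: double-center the squared dissimilarities, eigendecompose, scale
   the top eigenvectors by √λ. Goodness of fit is Kruskal stress-1.
3. **Online projection.** Each feedback step, the current mental state
   (CMS) pattern is placed on the *fixed* map by landmark MDS
   (de Silva & Tenenbaum): from its squared dissimilarities δ to the
   anchors, *x* = ½ Λ^(−1/2) Vᵀ (μ − δ), where μ are the column means of
   the squared anchor-distance matrix.
4. **Pattern strength.** On mean-centered vectors, the target-related
   intensity is the projection coefficient
   strength = (CMS·TMS)/(TMS·TMS) = *r* · ‖CMS‖/‖TMS‖: scaling the CMS by
   *k* leaves the similarity *r* (and the map position, under the
   correlation metric) unchanged and multiplies strength by exactly *k*.
5. **Displays.** A map view (CMS point, marker size = strength) and a
   circular thermometer view (one thermometer per state; only the target
   fills; a central arrow interpolates between target and best neighbour by
   dist = 1 − t/(t + nb), which lies in [0, 0.5]).
6. **Simulator.** Synthetic anchors with prescribed correlation structure,
   noisy trials, double-gamma-HRF block-design volume streams, and a
   navigating agent whose hidden state walks the anchor simplex — so the
   whole loop runs end-to-end without a scanner.

## Worked example

```bash
python examples/01_semantic_map.py
```

```
4 x 4 RDM (d = 1 - Pearson r):
[[0.    0.506 0.978 1.053]
 [0.506 0.    1.043 1.081]
 [0.978 1.043 0.    0.513]
 [1.053 1.081 0.513 0.   ]]

2-D semantic map coordinates (map units):
     happy: (+0.495, -0.000)
   content: (+0.410, +0.363)
     angry: (-0.347, -0.354)
       sad: (-0.557, -0.009)

Kruskal stress-1 = 0.0861
```

Same-valence states ('happy'/'content', 'angry'/'sad') sit at distance
≈ 0.5 (correlated patterns) and opposite-valence states near 1
(uncorrelated), so the map separates the two valence groups along its first
axis; stress 0.086 means the planar map reproduces the measured
dissimilarities well. `examples/02_pattern_strength.py` shows the
similarity/intensity dissociation, `03_feedback_displays.py` renders both
display geometries for one time point, and `04_closed_loop_session.py` runs
the full simulated session and prints within- and between-run navigation
improvement.

The same pipeline is scriptable from a shell:

```bash
semnf simulate --out-dir demo --seed 1
semnf rdm --patterns demo/anchors.tsv --out demo/rdm.tsv
semnf map --rdm demo/rdm.tsv --dims 2 --out demo/map.json
semnf session --map demo/map.json --anchors demo/anchors.tsv \
      --stream demo/agent_stream.tsv --out-dir demo/sess --run-boundary 20
```

Every command writes a manifest; `semnf session --from-manifest …` replays
a run bit-identically.

## Layout

- `src/semnf/rsa.py` — patterns, metrics, RDM, F-based voxel selection
- `src/semnf/mapping.py` — classical MDS, landmark projection, stress
- `src/semnf/feedback.py` — target selection, pattern strength, displays
- `src/semnf/realtime.py` — closed-loop driver, navigation metrics
- `src/semnf/synthetic.py` — ground-truth generators and the agent
- `src/semnf/io.py`, `src/semnf/cli.py` — text/NIfTI formats, manifests, CLI

See `docs/methods.md` for the model, parameter defaults and known
limitations.
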