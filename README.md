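# flyscreen

Quantitative machinery for genetic-modifier screening in the *Drosophila*
eye, aimed at studies of variably expressive CNVs (such as the autism-
associated 16p11.2 deletion) where many genes in a region interact to
modulate neurodevelopmental phenotypes. The package covers the four
quantitative stages such a screen needs, plus a synthetic-data generator so
every stage is testable with known ground truth:

1. **Eye scoring** (`flyscreen.eyescore`) — detect ommatidial centers in a
   grayscale eye-surface image and summarise the disorder of the hexagonal
   lattice into a phenotypic score *S*. For each interior ommatidium *i*
   with neighbour vector lengths *l₁…l₆* and sorted angular gaps Δθⱼ,

   dᵢ = w_L · CV(lⱼ) + w_A · (1/kᵢ) Σⱼ |Δθⱼ − 60°| / 60°,  S = 100 · mean(dᵢ).

   *S* = 0 exactly on a perfect hexagonal lattice, is invariant under rigid
   motions and uniform scaling, and increases with positional disorder.
2. **Epistasis classification** (`flyscreen.epistasis`) — a 2×2 factorial
   decision model for two-hit knockdowns. With Δ₁ = mean(AB) − mean(A) and
   Δ₂ = mean(B) − mean(control), the interaction contrast Δ₁ − Δ₂ is tested
   with a two-way ANOVA (df = 1): a significant negative contrast calls a
   suppressor, positive an enhancer; otherwise a significant B main effect
   calls an additive relationship. Suppressors whose two-hit flies are
   indistinguishable from control are flagged as full rescues.
3. **Enrichment** (`flyscreen.enrich`) — strict DE filtering
   (|log₂FC| > 1 and FDR < 0.05), parametric gene-set Z-scores
   Z = (S_m − μ)·√m / δ with Benjamini-Hochberg correction, homolog
   mapping, and a permutation test for cross-model overlap of DE genes.
4. **Network connectors** (`flyscreen.brainnet`) — enumerate *all*
   geodesics between seed genes on a (optionally weight-thresholded) gene
   interaction network, extract connector genes and per-edge criticality
   counts, and test connector annotation enrichment with a one-sided
   Fisher's exact test against random-seed controls.

`flyscreen.synth` generates every input with planted ground truth:
hexagonally packed eye images with controllable jitter/dropout/fusion,
replicate score tables with planted interaction classes, multi-model DE
studies with planted enriched terms and ~50% knockdown genes, and random
weighted networks. `flyscreen.pipeline` ties the stages together under one
master seed with a JSON run manifest; re-running a config reproduces
byte-identical tables.

## Worked example

```python
from flyscreen import synth, eyescore, epistasis

# score synthetic eyes at increasing lattice disorder
for sigma in (0.0, 1.0, 2.5):
    spec = synth.LatticeSpec(jitter_sigma=sigma, seed=42)
    image, truth = synth.generate_eye_image(spec)
    score, centers = eyescore.score_image(image, expected_spacing=10.0)
    print(f"sigma={sigma:3.1f} px  detected={centers.n:3d}  S={score.score:6.2f}")

# classify a planted suppressor pair
truth = synth.InteractionTruth("MAPK3_rl", "CORO1A_coro", "suppressor",
                               effect_a=9.0, effect_b=4.0,
                               interaction_shift=-8.0, within_sd=1.5,
                               n_replicates=12)
table = synth.generate_score_table([truth], control_mean=20.0, seed=7)
call = epistasis.classify_interaction(table)
print(f"pair={call.pair_id} class={call.interaction_class} "
      f"contrast={call.contrast:.2f} F={call.f_interaction:.1f} "
      f"p={call.p_interaction:.2e} full_rescue={call.full_rescue}")
```

prints

```
sigma=0.0 px  detected=400  S=  1.52
sigma=1.0 px  detected=346  S= 43.91
sigma=2.5 px  detected=216  S= 57.64
pair=MAPK3_rl:CORO1A_coro class=suppressor contrast=-6.30 F=78.5 p=2.45e-11 full_rescue=False
```

A jitter of zero leaves a near-perfect lattice (the residual 1.5 score
units come from sub-pixel detection error on a noisy image); at 2.5 px
jitter a quarter of the facets are no longer separable and the score
saturates high. The planted suppressor is recovered with a strongly
significant negative interaction contrast; it is not a full rescue because
the two-hit mean remains well above control.

The same operations are available from a shell:

```sh
flyscreen run --demo --out demo_run --seed 0     # full synthetic study
flyscreen score --images demo_run/images --spacing 10 --out scores.tsv
flyscreen screen --scores demo_run/scores.tsv --out calls.tsv
flyscreen page --de demo_run/de_tables/model1.tsv --sets demo_run/gene_sets.gmt --out page.tsv
flyscreen connectors --network demo_run/network_edges.tsv \
    --seeds demo_run/network_seeds.txt --annot demo_run/network_annotation.txt --out net/
```

## Layout

```
src/flyscreen/      synth, eyescore, epistasis, enrich, brainnet, io,
                    pipeline, cli
tests/              pytest suite (unit, property, and end-to-end checks)
scripts/            acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
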