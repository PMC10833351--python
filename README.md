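# gdvb — B-value prediction from graphlet degree vectors

`gdvb` predicts the *distribution* of atomic displacement parameters
(isotropic B values) over a protein structure from nothing but the model's
geometry.  It is aimed at structural biologists and crystallographers who
want geometry-based starting B values for refinement, a sanity check on
deposited ADPs, or mobility estimates for predicted models that carry no
experimental B column.

## The model

Treat every (heavy) atom as a node and connect two atoms by an edge when
their distance is below a cutoff (5.0 Å by default).  For each node, count
how many times it *touches* each of the 15 orbits O₀…O₁₄ of the connected
graphlets on 2–4 nodes (edge; 3-path and triangle; 4-path, 3-star, 4-cycle,
paw, diamond and K₄).  The resulting per-atom count vector is the graphlet
degree vector (GDV); its first component O₀ is the plain contact number.

With per-structure z-scored B values as the response and column-z-scored,
neighbourhood-smoothed GDV components as predictors, the GDV model is the
multiple linear regression

```
B_n = b₀ + Σₖ βₖ · O_{n,k},   k = 0 … 14,
```

fit by ordinary least squares.  The baseline *contact model* uses O₀ alone;
its published form `B_p = −0.64 · O₀` (intercept 0, cutoff 7.0 Å) ships as
the built-in `contact` preset.  Both models predict normalized B values;
mapping back to Å² requires a user-supplied mean and sd and is reliable
only to the extent those moments are known.

As distribution-level QC, the B values of a well-refined model follow a
shifted inverse gamma distribution (SIGD) with density ∝
`(B − B₀)^(−α−1) · exp(−β/(B − B₀))`, where the shift is fixed at
B₀ = 0.9 × min(B) and shape α and scale β are estimated by maximum
likelihood.

## Worked example

Generate twelve 500-atom synthetic structures whose B values come from a
known linear GDV model plus Gaussian noise (σ = 0.5), then cross-validate
both model kinds (folds split by structure, never by atom):

```sh
$ gdvb simulate --n-atoms 500 --n-entries 12 --noise-sd 0.5 --seed 7 --out-dir entries
wrote 12 synthetic entries to entries

$ gdvb evaluate entries/*.pdb --model gdv --cutoff 5.0 --folds 4 --seed 0 --out eval_gdv.tsv
12 entries: mean r = 0.9339, median = 0.9344, min = 0.9263, max = 0.9405

$ gdvb evaluate entries/*.pdb --model contact --cutoff 7.0 --folds 4 --seed 0 --out eval_contact.tsv
12 entries: mean r = 0.8273, median = 0.8328, min = 0.7984, max = 0.8599
```

The per-entry numbers are Pearson correlations between predicted and
reference normalized B values for each held-out structure; the richer
wiring information in the GDV raises the mean correlation over the
contact-number baseline (0.93 vs 0.83 here).  Fitting on all entries also
reports the |t|-statistic variable importance (most important variable
scaled to 100):

```sh
$ gdvb fit entries/*.pdb --out gdv.coeffs --importance-out imp.tsv
fit gdv model on 6000 atoms from 12 structures; R^2 = 0.8728
```

SIGD QC from the Python API:

```pycon
>>> from gdvb import SIGDParams, fit_sigd, sigd_sample
>>> draws = sigd_sample(SIGDParams(alpha=4.0, beta=30.0, b0=12.0), n=5000, seed=1)
>>> p = fit_sigd(draws)
>>> print(f"alpha={p.alpha:.3f} beta={p.beta:.3f} b0={p.b0:.3f}")
alpha=3.556 beta=24.377 b0=12.491
```

(The fitted shift is 0.9 × the sample minimum by definition, which is why
it does not coincide with the generating shift; see `docs/methods.md`.)

Other subcommands: `gdvb gdv` (per-atom orbit table), `gdvb predict`
(apply a coefficient file or preset, optionally writing a PDB with
predictions in the B column), `gdvb qc` (entry-level dataset filters).

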