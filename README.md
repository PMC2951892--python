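# eesnet

Affine steady-state models of gene influence networks.

Given expression profiles of a wildtype and of `m` single-knockout mutants of
a chosen *internal* gene set, the `m+1` steady-state points define a unique
`m`-dimensional affine plane in gene-expression space. `eesnet` fits that
plane (the *effective empirical subnetwork*), uses it to

* **predict** the full expression vector of unseen mutants (e.g. double
  knockouts) by clamping internal genes and solving the fitted affine
  relations, and
* **steer** the network: project a prescribed target state onto the plane to
  obtain the internal-gene settings whose realized equilibrium lands as close
  as possible to the target,

and validates predictions against replicate measurements with per-gene
one-sample t-tests. A clustered Hill-function ODE simulator with designed
stable equilibria ships as ground truth for end-to-end study.

## Layout

| Module | Purpose |
| --- | --- |
| `eesnet.influence_network` | synthetic clustered Hill-function network generator (stable-by-construction Jacobian, exact designed equilibrium) |
| `eesnet.affine` | exactly-linear surrogate network with closed-form clamped equilibria (test oracle) |
| `eesnet.steady_state` | clamped steady-state solving (nonlinear least squares), knockout panels, viability |
| `eesnet.ees_core` | affine plane fit, internal inter-relations, mutant prediction |
| `eesnet.steering` | plane projection and realized-equilibrium evaluation |
| `eesnet.stats_compare` | wildtype rescaling, knockout zeroing, replicate t-tests, deviation histograms |
| `eesnet.io` / `eesnet.cli` | TSV/JSON/YAML formats and the command-line surface |
| `eesnet.pipeline` | end-to-end seeded synthetic studies |

## CLI

```sh
eesnet simulate --seed 7 --out net.json
eesnet knockouts --network net.json --out-expr panel.tsv --out-viability viab.tsv
eesnet fit --panel panel.tsv --internal g4,g8,g9,g12,g16,g18 --out ees.json
eesnet predict --ees ees.json --clamp g4=0 --clamp g8=0 --out pred.tsv
eesnet steer --ees ees.json --network net.json --target target.tsv --out steer.json
eesnet compare --table expr.tsv --sheet samples.tsv --ees ees.json \
    --pair fnr,arcA --out-prefix out/dko
eesnet replicate-synthetic --seed 3 --out summary.json
```

Expression tables are genes x samples TSV (CSV accepted on read) with a
sample sheet (`sample`, `condition`, `knocked_out_genes` columns). Networks,
fitted models and steering results are versioned JSON.

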