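# oakwood

Statistical toolkit for studying wood anatomical trait variation of
co-occurring tree species along environmental gradients — built around the
analysis style used for Mexican oaks (*Quercus*, sections *Quercus* and
*Lobatae*) sampled across an aridity gradient. It is aimed at plant
ecophysiologists and comparative biologists who have individual-level wood
measurements, plot climate data, a presence–absence matrix and a
phylogeny, and want the full chain from raw traits to phylogenetically
informed inference.

The package covers:

- **Trait derivation** — hydraulic variables from vessel measurements:
  composition index S = VA/VF, lumen fraction F = VF·VA, vulnerability
  index VI = VD/VF, relative hydraulic conductivity RC = r⁴·VF
  (r = VD/2); fibre total diameter F_D = F_L + 2F_W; wood density by
  water displacement; leaf-habit classification from annual canopy
  foliage series; the UNEP aridity index (humid at AI ≥ 0.65),
  Hargreaves–Samani PET, and an iterative VIF ≤ 10 climate-variable
  screen.
- **Phenotypic plasticity** — the relative distance plasticity index
  RDPI = Σ(d_ij→i′j′/(x_i′j′ + x_ij))/n over cross-plot individual
  pairs, bounded [0, 1]; per-section plot-pair RDPI matrices; multiple
  regression on distance matrices (MRM) against geographic and
  standardized environmental Euclidean distances, with significance from
  5000 joint row/column permutations of the response; Welch t-tests
  between sections.
- **Species co-occurrence** — the exact hypergeometric (probabilistic)
  model of pairwise co-occurrence, classifying each pair as a positive,
  negative or random association at α = 0.05.
- **Phylogenetic comparative methods** — Felsenstein's independent
  contrasts with through-origin correlations, PCA on traits or contrasts,
  Blomberg's K with a 999-shuffle randomization test, Brownian-motion
  PGLS with AIC model selection (and the OLS counterpart), and a
  simulation-based phylogenetic ANOVA (1000 simulations, Holm-adjusted
  post hoc tests).
- **Synthetic data** — a seeded generator reproducing the study's
  sampling frame (21 species on a pure-birth tree in 2 sections and 3
  leaf-habit classes, 33 plots spanning AI 0.78–1.78, 5 individuals per
  species per plot, lognormal measurement noise, optional per-vessel
  measurements) with full ground truth, so every stage can be verified by
  parameter recovery.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

```python
from oakwood import simulate, traits, plasticity, phylo, cooccurrence

bundle = simulate.simulate_study(seed=42)
ind, plots = bundle["individuals"], bundle["plots"]

d = traits.derive_vessel_variables(ind["VD"], ind["VF"], ind["VA"])
ind = ind.assign(VI=d.VI, RC=d.RC)

# plasticity per species and trait
tab = plasticity.rdpi_table(ind, ["VD", "VF", "RC"])
print(tab.groupby("trait")["rdpi"].mean().round(3))

# section-level MRM: does environmental distance drive plasticity?
geo = plasticity.geographic_distance(plots)
env = plasticity.environmental_distance(plots, ["AI", "mtdq", "pwq"])
sect = bundle["species"].set_index("species")["section"]
reds = [s for s in sect.index[sect == "Lobatae"]]
mats = [plasticity.rdpi_plot_pair_matrix(ind, s, "VD", plots=list(plots["plot"]))
        for s in reds if ind[ind["species"] == s]["plot"].nunique() >= 2]
avg = plasticity.section_mean(mats)
resp = plasticity.DistanceMatrix(avg.labels, plasticity.rdpi_transform(avg.values))
fit = plasticity.mrm(resp, [geo, env], n_permutations=5000, seed=1)
print(f"MRM R2={fit.r_squared:.3f} P={fit.p_r_squared:.4f}")

# co-occurrence and phylogenetic signal
pairs, summary = cooccurrence.cooccurrence_table(bundle["presence"])
means = traits.species_means(ind, log10=True, columns=["VD", "VF", "WD", "H"])
sig = phylo.blomberg_k(bundle["tree"], means["VD"], n_randomizations=999, seed=1)
print(summary["total"], summary["positive"], f"K={sig.K:.3f} P={sig.p_value:.3f}")
```

Output (seed 42):

```
trait
RC    0.375
VD    0.119
VF    0.117
MRM R2=0.832 P=0.0002
210 26 K=0.238 P=0.011
```

Mean RDPI is low for the raw anatomical traits (≈0.12) and higher for the
fourth-power conductivity index RC — plasticity amplifies through derived
hydraulic variables. The red-oak RDPI distance matrix is strongly
explained by environmental distance (R² = 0.83; the permutation P of
2×10⁻⁴ is the smallest value 5000 permutations can resolve). The 21
species form 210 pairs, 26 positively associated under the generator's
shared niche response. Vessel diameter shows a weak but significant
phylogenetic signal (K = 0.24 with Brownian rate 0.01 plus environmental
and habit effects diluting the phylogenetic component).

A command-line interface mirrors the library
(`oakwood simulate`, `oakwood traits derive`, `oakwood plasticity mrm`,
`oakwood cooccur run`, `oakwood phylo signal`, `oakwood pipeline run
--config cfg.yaml`); the pipeline command chains every stage and writes
one CSV per result plus a manifest of versions, seeds and input
checksums.

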