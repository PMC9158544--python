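# symbionet

Analysis of quantitative plant–ectomycorrhizal (EM) fungal bipartite
networks: what does the web of root–symbiont interactions look like, and
which assembly process — neutral abundance matching, spatial co-occurrence,
their combination, or pure chance — best explains it?

The package is aimed at community ecologists working with host × fungal-OTU
interaction count matrices built from root-sample sequencing (reads rarefied
to a common depth and averaged per host species), together with plot-census
abundances, gridded quadrat occupancy, and phylogenies of both guilds.

## What it computes

**Structural metrics** of the count matrix `a_ij` (plants i = 1..I in rows,
fungal OTUs j = 1..J in columns, grand total F, realized links L):

- connectance `C = L/(I·J)`;
- interaction evenness `H = −Σ p_ij log₂ p_ij / log₂ F` with `p_ij = a_ij/F`;
- interaction asymmetry `A_i = Σ_j |d_ij| / k_i`,
  `d_ij = (s_ij − s_ji)/max(s_ij, s_ji)` from the two partners' dependences;
- complementarity specialization `H2′ = (H2max − H2)/(H2max − H2min)`;
- weighted nestedness WNODF (decreasing-fill rule, 0–100);
- Barber weighted bipartite modularity
  `Q = (1/F) Σ_ij (a_ij − r_i c_j / F) δ(g_i, g_j)`, maximised by label
  propagation with randomized restarts;
- per-species degree and strength.

**Null-model significance**: "swap"-style null networks that preserve row
sums, column sums and L exactly; empirical 95% intervals and add-one
permutation p-values.

**Assembly hypotheses** as interaction-probability matrices summing to one:
`Ab` (product of relative abundances), `Sp` (normalized quadrat
co-occurrence, hard zeros where species never co-occur), `AbSp` (their
renormalized elementwise product), `Null` (1/(I·J)), `Obs` (a_ij/F).

**Model selection**: the observed network as one multinomial draw of F
interactions; `AIC = −2 log L`, ΔAIC and Akaike weights
`w_i = exp(−ΔAIC_i/2)/Σ exp(−ΔAIC/2)` via `NetworkAssemblyModel(...).fit()`.

**Prediction**: a constrained randomization assigns F interactions by a
probability matrix (every species receives at least one), giving 95%
prediction intervals for each structural metric under each hypothesis.

**Phylogenetic signal**: Bray–Curtis partner dissimilarity vs patristic
distance (Mantel permutation test), and Blomberg's K / Pagel's λ for species
degree and strength (K by PIC randomization, λ by maximum likelihood with a
likelihood-ratio test against λ = 0; both cross-validated against
`phytools::phylosig` in the test suite).

**Synthetic communities**: log-normal abundances, spatially aggregated
occupancy on a 25 × 50 grid of 20-m quadrats, interaction counts drawn under
a chosen hypothesis, and Yule trees with λ-scaled Brownian traits — so the
whole pipeline is testable with known ground truth and no downloads.

## Worked example

```python
import symbionet as sn

# a virtual community assembled by spatial overlap
sim = sn.simulate_network(sn.CommunityScenario(generative_model="Sp", seed=1))
m = sim.network

ab = sn.build_ab(sim.plant_abundance, sim.fungus_abundance)
sp = sn.build_sp(sim.plant_occurrence, sim.fungus_occurrence)
hyps = {
    "Null": sn.build_null(m.I, m.J, m.row_labels, m.col_labels),
    "Ab": ab, "Sp": sp, "AbSp": sn.build_absp(ab, sp),
}
print(sn.NetworkAssemblyModel(m, hyps).fit().summary())
```

prints

```
Network assembly hypothesis comparison (multinomial likelihood)
================================================================
Observed network: 15 plants x 60 fungi, F=2000, L=256
Zero-probability policy: strict

 rank model   loglik  k     aic  delta_aic  weight
    1    Sp -615.136  0 1230.27          0       1
    2  AbSp -3240.88  0 6481.76    5251.49       0
    3  Null -3384.42  0 6768.84    5538.56       0
    4    Ab -3976.71  0 7953.43    6723.16       0

Best-supported hypothesis: Sp
```

The spatial-overlap hypothesis that generated the data wins decisively
(ΔAIC > 5000 to the runner-up, Akaike weight 1.00): every observed
interaction falls inside Sp's co-occurrence support, while the other
hypotheses spread probability over pairs that rarely or never interact.
Structural metrics for the same network:

```python
print(sn.compute_all_metrics(m, seed=0).as_dict())
# {'connectance': 0.2844, 'evenness': 0.7030, 'mean_asymmetry_fungi': 0.7534,
#  'specialization_h2': 0.4482, 'wnodf': 19.550, 'modularity': 0.4359}
```

The same analyses are available from the shell:

```sh
symbionet simulate --seed 1 --out community/
symbionet metrics community/interaction_matrix.tsv
symbionet run config.yaml --out report/
```

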