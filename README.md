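# traitlab

Bayesian reconstruction of ancestral bacterial cell-wall architecture, with
the surrounding comparative-genomics machinery: discrete-trait MCMC under
several rate-prior schemes, stepping-stone Bayes factors and correlated-
evolution tests, ancestral gene-order (synteny) reconstruction for the
*dcw* division and cell-wall synthesis cluster, and phylum-level
presence/absence pattern classification for outer-membrane genes.

## The scientific problem

Whether the last bacterial common ancestor (LBCA) was a monoderm (one
membrane, typically thick peptidoglycan) or a diderm (an extra outer
membrane, thin peptidoglycan) is a long-standing question in bacterial
evolution. Given a rooted phylogeny of extant bacteria and per-taxon
cell-wall traits, it can be posed as ancestral state reconstruction for a
continuous-time Markov chain: a k-state trait evolves along branches with
free, possibly asymmetric transition rates q_ij, and the quantities of
interest are the posterior rates and the marginal probability P(i) of each
state at named ancestors (the root, each phylum's last common ancestor).
Because the prior on rates matters for a deep, data-limited question, the
analysis is repeated under several prior schemes — a fixed exponential
(mean 10), uniform-hyperprior exponentials on two scales, and reverse-jump
variants that can tie rates together or pin them to zero — and the schemes
themselves are compared by stepping-stone marginal likelihoods on the
doubled-log Bayes-factor scale (BF > 2 positive, 5–10 strong, > 20 very
strong evidence). Correlation between the membrane and peptidoglycan traits
is tested by the classic dependent-vs-independent 4-state comparison. Two
independent lines of evidence round out the picture: the ancestral gene
order of the 17-gene *dcw* cluster (reconstructed here by per-adjacency
parsimony), and the distribution of 16 outer-membrane biogenesis genes
across phyla, which falls into four recurring patterns.

All pipeline stages run on synthetic data generated by the package itself,
so the whole analysis is exercisable and testable without downloads; the
same code accepts real Newick trees, trait TSVs, gene-order tables and
presence/absence matrices.

## Worked example

Simulate an 85-taxon Yule tree, evolve a binary membrane trait on it at the
rate magnitudes the real analysis infers (gain 2.4, loss 0.1, monoderm
root), and reconstruct the root state under the fixed-exponential scheme:

```python
from traitlab import simulate, mcmc, tree
from traitlab.ctmc import RateMatrix

t = simulate.simulate_tree(n_tips=85, seed=11)          # mean branch = 0.1
truth = RateMatrix(k=2, rates={(0, 1): 2.4, (1, 0): 0.1})
tips, true_states = simulate.simulate_trait(t, truth, seed=12, root_state=0)

t = tree.tag_mrca(t, "LBCA", sorted(t.taxa))
settings = mcmc.ChainSettings(iterations=110_000, burnin=10_000,
                              thinning=100, n_chains=2, seed=13)
summary = mcmc.sample_posterior(t, tips, mcmc.model_spec("E", 2),
                                tags=("LBCA",), settings=settings)
p0 = 100 * summary.mean_node_probs("LBCA")[0]
print(f"mean q01 = {summary.rate_mean((0, 1)):.3f}")
print(f"mean q10 = {summary.rate_mean((1, 0)):.3f}")
print(f"LBCA mean P(0) = {p0:.1f}%")
```

Output:

```
mean q01 = 4.444
mean q10 = 0.674
LBCA mean P(0) = 65.6%
```

Both posterior rate means sit above their truths (4.4 vs 2.4 and 0.67 vs
0.1): a single binary trait on 85 taxa carries limited information, so the
exponential(10) prior inflates the posterior means — which is exactly why
the real analysis compares five prior schemes. The root is still
reconstructed as state 0 (monoderm), the true root state of this
simulation. Averaged over replicates the machinery is well calibrated: the
central 95% posterior intervals cover the true rates at the nominal rate
(see `docs/methods.md` and the coverage experiment below). The same
entry points drive the model×root×trait grid (`traitlab.traits.run_grid`),
the correlation test (`traitlab.traits.correlation_test`), the *dcw*
reconstruction (`traitlab.synteny`) and the outer-membrane pattern tables
(`traitlab.patterns`); a thin `traitlab` command-line interface wraps each
stage (`traitlab asr`, `traitlab correlate`, `traitlab grid`,
`traitlab synteny`, `traitlab patterns`, `traitlab simulate ...`).

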