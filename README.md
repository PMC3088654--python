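# psnet — critical-threshold community detection for protein similarity networks

`psnet` turns a matrix of pairwise protein similarity scores (BLAST percent
identity, or any score in [0, 100]) into a family of unweighted networks,
finds the thresholds at which the network topology changes abruptly, splits
the resulting *critical network* into communities, and quantifies how well
the classifications obtained from different proteins agree.  It is aimed at
molecular evolution / phylogenetics work where groups of organisms are to be
recovered from sequence similarity alone, without any prior taxonomic input,
and at network scientists who want a reproducible implementation of the
underlying graph machinery.

## The method

Given sequences *i, j* with similarity S<sub>ij</sub> ∈ [0, 100], the scores
are first symmetrized, S<sub>ij</sub> ← min(S<sub>ij</sub>, S<sub>ji</sub>).
For a threshold σ the network M(σ) has an edge (i, j) iff S<sub>ij</sub> ≥ σ,
giving a nested family from the complete graph (σ = 0) to the edgeless one.

For each network, the **neighborhood matrix** M̂ holds the shortest-path
order d(i, j) of every pair (0 on the diagonal and, by convention, for
disconnected pairs); its largest entry is the diameter D.  Two networks α, β
on the same node set are compared by

&nbsp;&nbsp;&nbsp;&nbsp;δ(α, β) = (1/N²) Σ<sub>ij</sub> | d<sub>α</sub>(i,j)/D(α) − d<sub>β</sub>(i,j)/D(β) |

Sweeping σ in steps of Δσ = 1 and plotting δ(σ, σ+Δσ) exposes sharp peaks
where modules detach; the network at the largest peak σ<sub>max</sub> is the
critical network.  It is decomposed with the Newman–Girvan algorithm:
repeatedly remove the edge with the largest betweenness b<sub>ij</sub> (the
fraction of the N(N−1)/2 pair geodesics through it), recording the dendrogram
of splits.  δ(m, m+1) along the removal trace marks the branching events far
more sharply than the modularity Q, which is kept as a comparator and to
arbitrate among δ-flagged cuts.

Two classifications ϕ, ψ (mapped from sequences to organisms by majority
vote) are compared by the **congruence index** G(ϕ, ψ) = Q(ϕ, ψ)/R(ϕ, ψ):
of the R organisms present in both, Q is the maximal number placed in
corresponding communities under the best many-to-one community map.

## Worked example

Simulate a similarity matrix with three planted blocks of 10 sequences
(within-block scores ≈ 75, between ≈ 25, noise sd 3), scan it, and decompose
the network at a threshold between the two score modes:

```console
$ psnet simulate planted --seed 3 --out-prefix demo
[psnet] seed = 3
[psnet] wrote demo.matrix.tsv/.truth.tsv/.organisms.tsv

$ psnet scan --matrix demo.matrix.tsv --out-prefix demo
[psnet] peaks at sigma = [15.0, 18.0, 24.0, 27.0, 30.0, 32.0, 66.0, 69.0, 74.0, 77.0, 84.0]
[psnet] sigma_max = 15.0
[psnet] wrote demo.profile.tsv, demo.measures.tsv

$ psnet communities --matrix demo.matrix.tsv --sigma 50 --out-prefix demo50
[psnet] 3 communities, 0 unassigned nodes
[psnet] wrote demo50.nwk/.partition.tsv/.nbhd.tsv/.net
```

The scan peaks come in two clusters: σ ≈ 15–32, where between-block edges
disappear (the three blocks disconnect one after another), and σ ≈ 66–84,
where the blocks themselves dissolve.  Nothing happens in the quiet zone in
between — the network there is exactly the three planted blocks, and the
`communities` run at σ = 50 recovers them as 3 communities matching
`demo.truth.tsv`.  The very first peak (σ<sub>max</sub> = 15 here) is the
step at which the until-then complete graph loses its first edges and its
diameter jumps from 1 to 2; `docs/methods.md` discusses why this
renormalization spike dominates the profile for two-mode synthetic matrices
but not for real BLAST matrices, whose scores spread continuously.

The same analysis is available as a library:

```python
from psnet import PlantedSpec, planted_similarity, delta_profile, build_network
from psnet import gn_decompose, choose_partition

S, truth, organisms = planted_similarity(PlantedSpec(seed=3))
profile = delta_profile(S)            # integer sigma grid 0..100
net = build_network(S, 50)
part = choose_partition(gn_decompose(net), net)
assert part.equivalent(truth)
```

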