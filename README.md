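# treediscord

Quantify and visualize **incomplete lineage sorting (ILS)** and
**introgression/hybridization (IH)** signals on the internal branches of a
species tree, directly from gene-tree quartet frequencies.

## The problem

Phylogenomic species trees routinely carry branches where a large fraction
of gene trees disagree with the species topology.  Two biological processes
dominate such discordance: ILS (retention of ancestral polymorphism across
speciation events) and gene flow between non-sister lineages.  Around any
internal branch the gene trees fall into three topology classes with
frequencies `q1 ≥ q2 ≥ q3` (`q1 + q2 + q3 = 1`, `q1` the species-tree
topology).  Under the multispecies coalescent (MSC) the two minor classes
are equally frequent, each with probability `e^(-t)/3` for a branch of `t`
coalescent units; asymmetric gene flow inflates one minor class above the
other.  `treediscord` turns this pattern into two interpretable
percentages per branch:

* **ILS index** `L = e^(-t)` ∈ [0, 100%] — 100% at a zero-length branch
  (maximal discordance), < 1% once `t > 4.6`;
* **IH index** `H` ∈ [0, 50%] — the estimated proportion of the genome
  inherited from the minor parental lineage (the inheritance
  probability γ).

A 1-df chi-square test on the minor-class counts (`q2·n` vs `q3·n`, with
`n` the effective number of gene trees) decides whether discordance is
symmetric.  If `P > α` (pure ILS):

    L = ((q2 + q3) / 2) / (1/3),        ILS-e = q2 + q3

otherwise the symmetric part is attributed to ILS and the excess of `q2`
to gene flow:

    L = q3 / (1/3),   ILS-e = 2·q3,   IH-e = q2 − q3,
    H = (q2 − q3) / ((q1 − q3) + (q2 − q3))

`ILS-e`/`IH-e` are the fractions of all gene trees whose discordance each
process explains.  A branch with `L < 50%` and `H < 10%` (strictly:
`< 30%` / `< 5%`) can be considered well resolved.

The package reads ASTRAL/ASTER-annotated species trees (`q1/q2/q3`,
`f1/f2/f3`, `EN` in bracket comments or quoted labels), or computes the
quartet frequencies itself from a file of gene trees, and validates the
estimators with a built-in network-coalescent simulator supporting
arbitrary hybridization (admixture) events.

## Worked example

```sh
$ printf "((A,B)'[q1=0.6;q2=0.3;q3=0.1;EN=10000]',(C,D));\n" > species.nwk
$ treediscord analyze species.nwk
node_id	q1	q2	q3	n	chi2	P	ILS_i	IH_i	ILS_e	IH_e	category
N2	0.600000	0.300000	0.100000	10000	1000	1.8e-219	30.0	28.6	20.0	20.0	ih_conflict
```

Reading the row: of 10,000 informative gene trees, 60% match the species
topology and the minor classes are strongly asymmetric (30% vs 10%,
χ² = 1000, P ≈ 2e-219).  The symmetric share (2×10%) is ILS — an ILS index
of 30% (`t ≈ 1.2` coalescent units) explaining 20% of the gene trees — and
the 20-point excess of `q2` implies that ~28.6% of the genome of one child
lineage traces to the sister group (`ih_conflict`: the branch should not
be read as a clean bifurcation).

The same analysis from raw gene trees, plus a figure:

```sh
treediscord simulate --model simple --ils 0.368 --ih 0.4 -n 10000 --seed 1 --out sim
printf "((2,3),4,1);\n" > model.nwk
treediscord analyze model.nwk --genetrees sim.nwk --outgroup 1 --plot tree.svg
```

The SVG shows, at each annotated node, a three-bar chart of `q1/q2/q3`
(dashed line at 1/3 = maximal-ILS expectation; bars filled when the
asymmetry test is significant) and a label block with `n`, `P`, `ILS-i`,
`IH-i`, `ILS-e`, `IH-e`.

Other entry points: `treediscord count` (attach frequencies to a tree),
`treediscord sweep --grid paper` (the 11×11 estimator-validation grid),
`treediscord plot` (re-render an annotated tree).

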