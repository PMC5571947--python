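# citecascade

Network-based measurement of innovation diffusion in citation corpora.

When a new technique is introduced — a surgical procedure, a device, a
method — the articles that cite its founding publication, directly or
through chains of citations, form a **diffusion cascade**: the structural
fingerprint of how the innovation spread. `citecascade` extracts these
cascades from a citation corpus and quantifies, for each seed article *s*
and its cascade *C_s*:

* **broadcast popularity** — the citations *Cit_s* the seed received from
  cascade members, and the fraction *Cit_{s,year}* arriving within one
  year of publication;
* **structural virality** — the cascade size *SC_s*; the structural depth
  *sd_{C_s}*, the mean length of shortest directed paths over ordered
  member pairs connected by a directed path (deep cascades are
  multi-generational); and the structural width *sw_{C_s}*, the ratio of
  the mean number of second-step citations to the mean number of
  citations accrued by cascade members (0 for a star graph, large for
  widespread tree-like branching);
* **innovation value** — for groups of articles (e.g. specialties), an
  evidence-weighted index built on an 8-stage ordinal implementation
  funnel. With *p_cg* the count of group *g*'s publications at stage
  *c* ∈ {1,…,8} and *P_c* = Σ_g *p_cg*,

      i_g = 100 · u_g / max_g u_g,   where   u_g = Σ_c c · p_cg / P_c ,

  so the top-ranked group scores exactly 100.

Groups are ranked by the medians of their per-cascade metric
distributions (75th percentile as tie-break), pairs of distributions are
compared with Mann–Whitney U or Kolmogorov–Smirnov tests under
Benjamini–Hochberg FDR correction, and rankings are compared with
Spearman's ρ, Kendall's τ-b, and Kendall's W — all with permutation
p-values, exact by full enumeration for small group counts.

The package is aimed at scientometric and health-services researchers who
have (or can export) a citation table and want reproducible
cascade-shape and innovation-value rankings. A deterministic synthetic
corpus generator (star / chain / Galton–Watson branching cascades with
dates, specialty labels, and evidence categories) makes the whole
pipeline runnable without any proprietary bibliographic data.

## Worked example

Generate the built-in two-group demo corpus (10 viral Galton–Watson
cascades with offspring mean λ = 2 and late-stage evidence categories,
10 broadcast stars with k = 20 and early-stage evidence), then run the
pipeline:

```sh
citecascade synth --seed 0 --out-dir demo/corpus
citecascade metrics --nodes demo/corpus/nodes.csv --edges demo/corpus/edges.csv \
    --seeds demo/corpus/seeds.txt --out-dir demo/metrics
citecascade rank --metrics-csv demo/metrics/metrics.csv \
    --metrics size,depth,width --out-dir demo/rank
citecascade index --nodes demo/corpus/nodes.csv --out-dir demo/index
```

`demo/metrics/metrics.csv` starts:

```
seed_id,specialty,seed_citations,first_year_fraction,size,structural_depth,structural_width
broadcast-c000-0000,broadcast,20,1.0,21,1.0,0.0
```

— a star cascade: 20 first-generation citers, depth exactly 1 (every
citer is one step from the seed), width exactly 0 (no second-step
citations). The depth ranking (`demo/rank/ranking_depth.csv`):

```
group,median,p75,p90,tie_break
viral,2.6627906976744184,2.7341772151898733,2.741193548387097,none
broadcast,1.0,1.0,1.0,none
```

places the branching group first — its cascades are multi-generational —
and the accompanying Kolmogorov–Smirnov test
(`demo/rank/tests_depth.csv`) confirms the two depth distributions
differ (adjusted p ≈ 3.4 × 10⁻⁵). The innovation index
(`demo/index/innovation_index.csv`):

```
group,index
viral,100.0
broadcast,20.0
```

ranks the group whose evidence mass was planted at the final
implementation stage at exactly 100. Rankings can then be correlated
with `citecascade compare` (e.g. against an external procedure-volume
ranking supplied as a two-column CSV), which reports Spearman/Kendall
coefficients with exact permutation p-values and Kendall's W.

The same operations are available as a library
(`citecascade.extract_cascade`, `structural_depth`, `innovation_index`,
`rank_correlation`, …); see the module docstrings and
[docs/methods.md](docs/methods.md).

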