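# sigkin

Kinship and social-structure analysis for managed animal populations, built
around zoological studbooks — the longitudinal registries of births, deaths,
parentage and inter-institution transfers kept for captive breeding
programs. The package is aimed at population managers and behavioural
ecologists who want to ask, quantitatively: *how much of the variation in
reproductive success in a managed social species is predicted by who an
animal lives with — kin or non-kin — and could rearranging animals across
institutions improve it?* The worked system is the meerkat (*Suricata
suricatta*), a highly social mongoose managed in regional zoo networks, but
nothing in the machinery is species-specific.

## What it computes

**Kinship.** The genealogy is a directed acyclic graph (parent → child).
The coefficient of relatedness between two individuals is evaluated by the
path-additive rule: every path that ascends parent edges and then descends
child edges, never revisiting a node, contributes *k*^φ for a path of φ
edges (*k* = 0.5 between parent and child), and contributions add over
paths. A classical numerator-relationship implementation (the recursive
kinship-matrix construction) is included as an independent cross-check; the
two coincide exactly on pedigrees whose common ancestors are non-inbred.

**Standard inheritance graphs (SIGs).** Scalar relatedness in a growing,
incompletely documented genealogy is biased by record-keeping, so relatives
are instead classified structurally: by the sex string of the ascending
path (e.g. `FM` = mother's father) and the descent depth, giving ascendant
(I), lateral (II) and descendant (III) classes. A focal individual with
complete degree-φ ancestry has exactly 2^φ ascendant paths — four
grandparental paths even when inbreeding leaves only two grandparents — and
the classification preserves all relatedness information.

**Reproductive success** is *r*₍III₎: the sum of relatedness coefficients to
all descendants born in an accounting window (one child = 0.5, one
grandchild = 0.25), so fecund and sterile offspring are weighted
differently.

**Prediction.** For every focal-month, covariates count living relatives
per SIG class in the same zoo (local kin, α), in other zoos (non-local, β),
anywhere (global, α+β), and unrelated zoo-mates matching a relative's age
and sex (pseudo-kin, γ), alongside age, sex and group sizes. Recursively
partitioned regression models (ANOVA CART with minsplit = minbucket = 15,
cp = 0.01, 10-fold cross-validation pruning) are trained per variable set
and validated in an independent population. The decisive comparison is the
**split** model (α and γ as separate variables — kin-aware) against the
**sigma** model (α+γ merged — kin-blind): if kin and non-kin companions had
interchangeable effects, merging would cost nothing.

**Co-transfer tests** compare subsequent reproductive success after moving
animals together with same-sex littermates versus with matched unrelated
animals (Kruskal–Wallis), with heritability confound checks.

**Optimization.** A genetic/packing algorithm searches assignments of all
living animals to zoos — random seed arrangements refined by mutation and
elitist selection under historic-capacity and minimum-group-size
constraints — maximizing model-predicted 12-month per-capita *r*₍III₎.

A synthetic studbook generator with planted kin, pseudo-kin, age and
group-size effects (plus incest avoidance and mate availability, the
mechanisms that give kin and non-kin companions distinct roles) makes every
stage testable end-to-end; see `docs/methods.md` for the model and its
limits.

## Worked example

```python
from sigkin import *
from sigkin.studbook_io import StudbookRecord, StudbookTable

rows = [("GM","F",None,None,0),  ("GS","M",None,None,0),
        ("PGM","F",None,None,0), ("PGS","M",None,None,0),
        ("DAM","F","GM","GS",24),("UNC","M","GM","GS",24),
        ("SIRE","M","PGM","PGS",24),
        ("FOC","F","DAM","SIRE",60),
        ("KID","F","FOC",None,100),("GKID","M","KID",None,130)]
table = StudbookTable(records={
    r[0]: StudbookRecord(r[0], sex=r[1], dam_id=r[2], sire_id=r[3],
                         birth_month=r[4], birth_institution="ZooA")
    for r in rows})
g = build_kdag(table)
print("r(FOC, DAM)  =", path_relatedness(g, "FOC", "DAM"))
print("r(FOC, UNC)  =", path_relatedness(g, "FOC", "UNC"))
print("complete d2? ", has_complete_sig(g, "FOC", 2))
sig = build_sig(g, "FOC", 2)
for key in sorted(sig.members,
                  key=lambda k: (len(k.ascent), k.ascent, k.descent_depth)):
    print(f"  class {key.sig_class:<3} {key.label():<4} -> {sorted(sig.members[key])}")
print("r_III over months 90-140 =", reproductive_success(g, "FOC", (90, 140), table))
```

prints

```
r(FOC, DAM)  = 0.5
r(FOC, UNC)  = 0.25
complete d2?  True
  class III D1   -> ['KID']
  class III D2   -> ['GKID']
  class I   F    -> ['DAM']
  class I   M    -> ['SIRE']
  class I   FF   -> ['GM']
  class II  FF1  -> ['UNC']
  class I   FM   -> ['GS']
  class II  FM1  -> ['UNC']
  class I   MF   -> ['PGM']
  class I   MM   -> ['PGS']
r_III over months 90-140 = 0.75
```

The focal is related to its mother by the single length-1 path (0.5) and to
its uncle by two length-3 paths through the shared grandparents (0.25). Its
SIG places each ancestor under a unique sex-string key, the uncle under
both lateral keys that reach him, and the child and grandchild in the
descendant classes — whose births inside the window sum to
*r*₍III₎ = 0.5 + 0.25 = 0.75.

## The analysis pipeline

Numbered drivers under `analysis/` run the full study on synthetic
studbooks and write tables under `results/`:

| driver | what it does |
|---|---|
| `01_simulate_studbooks.py` | generate and clean the two regional-scale populations |
| `02_kinship_bias.py` | documentation bias of classical mean relatedness |
| `03_fit_models.py` | six model specifications, external validation table |
| `04_forecasting.py` | forecast accuracy at horizons up to 24 months |
| `05_cotransfer.py` | littermate vs pseudo-sibling co-transfer tests |
| `06_optimize_groups.py` | constrained group-structure optimization |

Each accepts `--seed` and `--out`; e.g.
`python analysis/03_fit_models.py --seed 1`.

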