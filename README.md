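# biofluidminer

Semi-automated literature mining for putative disease biomarkers in specific
biofluids (serum, plasma, urine, saliva, bile, ...).

Keyword searches of PubMed return far more abstracts than a curator can read,
and a marker that is mentioned *often* near a disease term is not necessarily
*enriched* there — many proteins are discussed everywhere. `biofluidminer`
implements the positive/negative corpus contrast that fixes this: for each
disease–biofluid pair it takes a **positive set** S1 of abstracts retrieved
with `<disease> AND <biofluid>` and a **negative set** S2 retrieved with
`<biofluid> NOT <disease>`, tags gene/protein mentions, normalizes them to
consensus gene symbols through an alias dictionary, and ranks every marker
found in S1 by an enrichment z-score. It is aimed at biomedical-informatics
researchers compiling candidate biomarker lists (and informative priors for
downstream disease models) from literature snapshots.

## The score

Let Sp be the set of dictionary-mapped markers mentioned at least once in S1.
For each marker *P* in Sp, counting **distinct abstracts** (a marker counts
once per abstract no matter how often it is repeated):

```
df1(P) = # S1 abstracts mentioning P          dft(P) = df1(P) + df2(P)
df2(P) = # S2 abstracts mentioning P

ex(P)  = dft(P) · |S1| / (|S1| + |S2|)        expected S1 documents
ev(P)  = df1(P)                               observed S1 documents
f(P)   = (ev(P) − ex(P)) / dft(P)             normalized difference ∈ [−1, 1]
Z(P)   = (f(P) − mean(f)) / SD(f)             standardized over Sp
```

SD(f) is the sample standard deviation (divisor n−1). Markers with Z
strictly above a threshold τ (default 1.0) are called significant, then
partitioned against curated known-marker lists (OMIM, CAGE, Genes & Disease,
EDRN, expert lists) into *known* and *new* discoveries, summarized per
biofluid, and crossed into a marker × biofluid specificity matrix.

## Worked example

Generate a seeded synthetic corpus pair (one enriched marker, `MARKER1`,
mentioned in 30% of positive vs 0.1% of negative abstracts, against ten
background markers mentioned equally often in both sets), then score it:

```
$ biofluidminer simulate --outdir demo --seed 5 --n1 40 --n2 400
$ printf 'MARKER1\tO,X\nBG03\tC\n' > demo/known.tsv
$ biofluidminer score --positive demo/s1.medline.txt --negative demo/s2.medline.txt \
    --dictionary demo/dictionary.tsv --known demo/known.tsv \
    --disease "breast cancer" --biofluid serum --outdir demo/out
```

The ranked score table (`demo/out/scores_breast-cancer_serum.tsv`):

```
symbol   df1  df2  dft  ex            ev  f             z             significant
MARKER1  9    1    10   0.9090909091  9   0.8090909091  2.192603871   1
BG01     1    2    3    0.2727272727  1   0.2424242424  -0.137037742  0
BG06     2    4    6    0.5454545455  2   0.2424242424  -0.137037742  0
...
```

`MARKER1` appears in 9 of 40 positive abstracts but only 1 of 400 negative
ones; under uniform spread its 10 total documents would put only ~0.91 in S1,
so f ≈ 0.81 and it stands 2.19 standard deviations above the mean marker —
the only significant hit. The background markers sit near f ≈ ex/dft noise
and are correctly rejected. The per-pair summary
(`demo/out/summary.tsv`, printed by `biofluidminer report --summary ...`)
shows 7 markers found, 1 known, 1 significant, and that the one significant
marker is the known one (0% new discoveries in this toy pair).

Real corpora are consumed the same way: PubMed MEDLINE flat-text exports for
`--positive`/`--negative`, a protein-nomenclature dictionary (id, symbol,
RefSeq id, semicolon-separated aliases), and optionally tagged-SGML output
from an external NER tagger via `--tagger sgml`. A YAML config plus
`biofluidminer run` scores many disease–biofluid pairs in one call.

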