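# isodom — protein domain isotypes

Protein domains are usually treated as invariant building blocks with fixed
function. In practice the *same* Pfam domain occurs across a proteome — and
across the isoforms of a single gene — as length variants with measurably
different structure and function. `isodom` detects and analyses these
**domain isotypes** from standard inputs: `pfam_scan.pl` output, PDB
coordinate files, domain–motif interaction tables, gene-set collections and
transcript-level TPM matrices.

## The classification at its core

For one domain occurrence, `pfam_scan` reports the alignment between the
profile model (length `hmm_length`, matched over `hmm_start..hmm_end`) and
the query sequence (matched over `seq_start..seq_end`). From these:

```
trunc_size     = max(hmm_start − 1, hmm_length − hmm_end)
indel_size     = (seq_end − seq_start + 1) − (hmm_end − hmm_start + 1)
trunc_fraction = trunc_size / hmm_length
indel_fraction = indel_size / hmm_length          (+ = insertion, − = deletion)
overall_variation = max(trunc_fraction, |indel_fraction|)
```

With thresholds of 0.1 (inclusive ≥) the occurrence gets exactly one of five
isotypes — **reference** (neither feature), **complex** (both),
**truncation**, **insertion**, **deletion** — simplified to reference /
non-reference for downstream tests.

Downstream analyses, each in its own module:

| module | analysis |
|---|---|
| `pfamscan_io` | tolerant parsing/writing of `pfam_scan.pl` tables, Domain-only filter |
| `isotype_core` | the metrics and five-way classification above |
| `length_modes` | KDE mode counting of per-domain length distributions (occupancy-constrained local maxima) |
| `struct_compare` | BLOSUM50-guided Kabsch superposition, backbone RMSD, TM-score (`d0 = 1.24·(L−15)^⅓ − 1.8`), 9×21 sampling, ≥3-comparison averaging, unrelated-domain baseline |
| `motif_clusters` | optimal-string-alignment distances, complete-linkage clustering cut at h=4, 80%-purity isotype specificity, exact k×2 Fisher test |
| `enrichment` | Fisher overlap tests with BH-FDR, and isotype-skew testing by preranked GSEA on genes ranked by decreasing average overall variation (NES > 0 ⇒ non-reference end) |
| `expression_switches` | major (most-expressed coding) transcript per tissue/cell type and domain-isotype switch detection |
| `synthetic_data` | seeded generators with planted ground truth for all of the above |

## Worked example

```python
from isodom import annotate, filter_domains, read_pfamscan
from isodom.synthetic_data import simulate_pfamscan

hits, truth = simulate_pfamscan(n_records=500, seed=20)   # or read_pfamscan("scan.txt")
table = annotate(filter_domains(hits))
print(table["isotype"].value_counts().to_dict())
print((table["isotype"].to_numpy() == truth["planted_isotype"].to_numpy()).mean())
```

prints

```
{'reference': 107, 'insertion': 103, 'deletion': 102, 'truncation': 95, 'complex': 93}
1.0
```

— 500 synthetic domain records drawn from a uniform five-way isotype mix,
every planted category recovered exactly (fractions are generated clear of
the 0.1 boundary, so classification is unambiguous). The same flow works on
real `pfam_scan.pl` output via the CLI:

```bash
isodom classify scan.txt --out annotations.tsv
isodom modes annotations.tsv --min-size 0.1 --out modes.tsv
```

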