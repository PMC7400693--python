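# clonokit

Single-cell immune receptor repertoire analysis for 10x Genomics V(D)J
data: from `filtered_contig_annotations.csv` (or AIRR Rearrangement TSVs)
to paired-chain clonotype calls, clonal-architecture statistics, diversity
and overlap estimators, clone-size-distribution clustering, and joins onto
per-cell expression metadata.

## Who it is for

Immunologists and single-cell analysts who have run Cell Ranger's TCR or
Ig enrichment workflow and want to couple clonality with transcriptomic
clustering. clonokit is deliberately expression-framework-neutral: it
consumes and produces plain tables keyed by cell barcode, so any toolkit
that can export `(barcode, cluster, dim1, dim2)` interoperates.

## What it computes

**Clonotype calling.** Contigs are filtered (productive, high-confidence,
called cell, locus of interest, ≥ 1 UMI) and merged per barcode. Each cell
receives four identifiers of increasing stringency — gene segments
(`CTgene`), CDR3 nucleotide (`CTnt`), CDR3 amino acid (`CTaa`), and
gene + nucleotide (`CTstrict`). The two loci (TRA/TRB, or IGH/IGK·IGL) are
joined by `_`, with a literal `NA` for a missing chain, so a beta-only
cell reads `NA_CATSATLRVVAEKLFF`. Dual-alpha cells keep their top two
chains by UMI, joined by `;`.

**Clonal architecture.** Unique-clonotype quantification (raw or % of
library), abundance tables, CDR3 length distributions (per chain or
combined per cell), clonal homeostasis (repertoire space per
clone-proportion class, Rare ≤ 10⁻⁴ through Hyperexpanded ≤ 1), and
clonal proportion (cells occupied by abundance ranks 1–10, 11–100, …).

**Diversity and overlap.** Per sample: Shannon entropy
H = −Σ pᵢ ln pᵢ, inverse Simpson 1/Σ pᵢ², bias-corrected Chao1
S_obs + F₁(F₁−1)/(2(F₂+1)), and ACE with rare-class threshold 10.
Between samples: the overlap coefficient |A∩B|/min(|A|,|B|) and the
Morisita-Horn index 2Σxᵢyᵢ/[(Σxᵢ²/X² + Σyᵢ²/Y²)XY]; clone-size
distributions are compared by base-2 Jensen-Shannon divergence over
log-spaced size bins and clustered with average linkage (Newick export).

**Expression linkage.** Left-joins clonotype calls onto cell metadata,
bins cells by clone frequency (absolute counts or proportions),
highlights chosen clonotypes, computes group composition per cluster, and
emits alluvial flow tables. Splitting by any categorical column turns
every statistic into a per-cluster/per-tissue analysis.

**Synthetic data.** A seeded generator produces contig files (both
dialects), matched metadata, and a planted-truth table, with configurable
clone-size models (power law, lognormal, uniform), dual-alpha rate, chain
dropout and spurious-contig rate — every analysis is testable end to end
with no external data.

## Worked example

```python
import clonokit as ck

spec = ck.SimSpec(n_cells=500, seed=42, sample_name="demo")
contigs, truth = ck.simulate_repertoire(spec)
filt = ck.filter_contigs(contigs, ck.FilterSpec.default("TCR"))
rep = ck.combine_receptors([filt], ["demo"])
cv = ck.count_clonotypes(rep, call_by="aa")["demo"]

ck.quantify_unique(cv, scaled=True)   # (330, 66.0)
ck.shannon_index(cv)                  # 5.5679
ck.inverse_simpson(cv)                # 183.02
ck.chao1(cv)                          # 919.0
ck.ace(cv)                            # 1083.8
ck.clonal_homeostasis(cv)
# {'Rare': 0.0, 'Small': 0.0, 'Medium': 0.882, 'Large': 0.118,
#  'Hyperexpanded': 0.0}
```

Reading: of 500 cells, 330 distinct clonotypes (66% of the library —
a diverse repertoire). Shannon entropy 5.57 nats against a maximum of
ln 330 ≈ 5.80; the inverse Simpson of 183 says the repertoire behaves
like ~183 equally sized clones. Chao1 (919) and ACE (1084) estimate the
richness including clones the 500-cell sample missed. No clone exceeds
10% of the repertoire, so the hyperexpanded class is empty; 88% of
clonal space is held by medium clones (0.1–1% each).

The first abundance rows show the dual-alpha convention — two alpha
CDR3s joined by `;`, then `_`, then the beta chain:

```
                          clonotype_key  count  proportion
CSDETRRLRIWVF;CEKPVYLPWPTF_CERFPALSIHKF     13       0.026
        CCLDCLYERIKLSAF_CGPPAHLSAESVYYF     12       0.024
```

## Command line

```bash
clonokit simulate --samples 3 --cells 2000 --seed 1 --outdir data/
clonokit combine --contigs data/S1.filtered_contig_annotations.csv \
    --sample S1 --outdir rep/
clonokit metrics   --repertoire rep/ --outdir out/
clonokit diversity --repertoire rep/ --out out/diversity.tsv
clonokit overlap   --repertoire rep/ --method jsd --out out/jsd.tsv
clonokit join      --repertoire rep/ --meta data/S1.metadata.tsv \
    --out out/joined.tsv
clonokit run       --config run.yaml --outdir out/   # whole pipeline
```

Every metric has a TSV export; the `run` subcommand writes all tables
plus a JSON manifest (version, config hash, seed).

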