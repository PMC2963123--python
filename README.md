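# phylopair

Operon-aware protein-family phylogenetics: a tested re-implementation of a
comparative-genomics workflow for assigning functions to an ATPase family by
pairing it with candidate transporter partners.

The pipeline covers:

- **catalog** — a packaged 212-protein homologue catalog (18 clusters) with
  per-cluster summaries (member counts, half-up rounded mean sizes, maxima,
  single- vs double-domain architecture),
- **redundancy** — greedy longest-first filtering of redundant,
  near-identical and fragmentary sequences at a percent-identity cutoff
  (default 90%),
- **align** — affine-gap Needleman–Wunsch (BLOSUM62, gap open 11 / extend 1),
  progressive multiple alignment on an NJ guide tree, Poisson-corrected and
  score-based distances, reference-coordinate mapping,
- **treebuild** — classical Saitou–Nei neighbor joining, Newick IO,
  patristic distance matrices,
- **congruence** — a quantitative formalization of paired-tree coevolution
  verdicts: Robinson–Foulds distance and cophenetic (patristic) correlation
  over an operon-derived leaf pairing, with a permutation null
  (B-side shuffle, p = (1 + #{null ≥ obs}) / (n_perm + 1)),
- **context** — operon calling (same strand, intergenic gap ≤ 200 bp by
  default) and same-operon / elsewhere-in-genome / absent association
  profiling with family exclusions,
- **motif** — one-occurrence-per-sequence EM motif discovery (candidate-window
  seeding, pseudocount 0.01), degenerate pattern matching
  (e.g. `GKGGVGK[TS]`, `GXGXXG`), per-group residue conservation reports,
- **hydropathy** — Kyte–Doolittle sliding-window profiles (window 19),
  alignment-averaged hydropathy/amphipathicity/similarity plots, and a simple
  TMS caller,
- **simulate** — synthetic ground truth: Yule trees, Poisson-style sequence
  evolution, shared-tree vs independent family pairs, and operon-structured
  genome annotation tables with planted-truth records.

## CLI

One entry point with subcommands:

```sh
phylopair summarize                     # per-cluster catalog summaries
phylopair filter in.faa --cutoff 0.90 --out kept.faa
phylopair align in.faa --out aligned.faa
phylopair tree --distances d.tsv --out tree.nwk
phylopair coevolve --tree-a a.nwk --tree-b b.nwk --pairs pairs.tsv \
    --nperm 999 --seed 1
phylopair context --features features.tsv --family-a arsA --family-b acr3 \
    --exclude arsB,arsP
phylopair motif discover seqs.faa --width 12 --nstarts 10 --seed 1
phylopair motif scan seqs.faa --pattern "GKGGVGK[TS]"
phylopair hydropathy seqs.faa --window 19
phylopair simulate pair --n-taxa 12 --mode shared_tree --seed 1 --outdir sim/
phylopair simulate genomes --n-genomes 10 --seed 1 --outdir sim/
phylopair run --config pipeline.yaml --outdir out/
```

`phylopair run` takes a plain key-value YAML config, e.g.:

```yaml
seed: 42
simulate: {n_taxa: 12, mode: shared_tree, branch_jitter_sigma: 0.1}
congruence: {n_perm: 999}
motif: {width: 12, n_starts: 10}
```

and writes each stage artifact plus a `manifest.json` with SHA-256 hashes;
reruns with the same seed are byte-identical.

## Conventions and caveats

- Reference residue positions and genome coordinates are 1-based; alignment
  columns are 0-based.
- Percent identity excludes terminal-gap columns (fragment-friendly).
- NJ ties are broken lexicographically; negative branch-length estimates are
  clamped to zero with the deficit moved to the sibling branch.
- The redundancy filter is a surrogate for an unpublished screening tool;
  note that retained-set size is *not* strictly monotone in the cutoff for
  any greedy sequential filter (see `tests/test_redundancy.py` for a pinned
  counterexample).
- The cluster-10 mean size in the packaged catalog computes to 419, while
  the source running text prints 410; the derived value is reported as-is.
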