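# phyloprofiler

Comparative-genomics trait mining for microbial genome collections:

- **PPP (partial phylogenetic profiling)** — given a YES/NO trait profile
  over a genome collection (e.g. "encodes a marker gene cluster"), score
  every protein of a genome by walking its ranked similarity hit list and
  finding the score cutoff at which the set of genomes hit best matches the
  profile. The statistic is the log10 binomial upper tail
  `score = log10 P(X ≥ y), X ~ Binomial(n, p)`, where at a cutoff the
  prefix covers `n` distinct genomes, `y` of them trait-positive, and `p`
  is the trait prevalence. The minimum over cutoffs (most negative = most
  enriched) ranks the proteins and nominates trait-linked families together
  with working family cutoffs.
- **SIMBAL** — the same optimal-cutoff statistic applied to every
  subsequence window of a probe protein against a protein family split into
  TRUE/FALSE partitions by the genome trait (fragments removed, thinned to
  ≤ 80% pairwise identity). Scores are displayed as `−log10` tail on a
  triangular window-center × window-length grid whose apex is the
  full-length protein; plumes rising from short windows localize the
  residues that carry the trait association (e.g. a cofactor-binding site).
- **Short-ORF / motif scanning** — six-frame translation (table 11) for
  complete start-to-stop ORFs in a precursor-peptide size range, filtered
  by an invariant C-terminal motif, plus per-column alignment conservation
  statistics. This recovers ribosomally produced precursor peptides that
  gene callers miss.
- **Synthetic collections** — a seeded generator of genome collections with
  planted marker systems, trait-dependent paralog families carrying a
  diagnostic subsequence window, background families, and precursor genes
  in contigs, with truth labels, so the whole pipeline is testable
  end-to-end without downloads.

Intended for bioinformaticians studying sparsely distributed gene systems
(cofactor biosynthesis clusters, bacteriocin-like systems) who want the
profiling/window-mapping machinery as a tested library and CLI.

## Worked example

Generate a 40-genome collection (10% trait prevalence, i.e. 4 trait-positive
genomes) with model-based hit tables, then rank the proteins of a
trait-positive genome:

```sh
phyloprofiler synth --seed 7 --out data
phyloprofiler ppp --proteins data/proteins.faa --genome-map data/genome_map.tsv \
    --profile data/trait.tsv --hits data/hits.tsv --genome g023 --out ppp_g023.tsv
head -9 ppp_g023.tsv
```

```
# genome: g023
# prevalence: 0.100000
# engine: tabular
# version: 0.1.0
query	yes	total	depth	score
dep0.g023.1	4	4	8	-4.000000
dep0.g023.2	4	4	7	-4.000000
dep0.g023.3	4	4	7	-4.000000
dep1.g023.0	4	4	8	-4.000000
```

The top of the table is filled by the planted trait-dependent paralogs
(`dep*`) and marker genes: each reaches a cutoff covering all 4
trait-positive genomes and only those (`yes = total = 4`), scoring
`4·log10(0.1) = −4.0` — the best score available at this prevalence —
while `depth > total` counts the paralogous hits traversed. Background
families score closer to 0 and sort below.

Scan the contigs for short precursor genes by their invariant C-terminal
motif (`x` matches any residue):

```sh
phyloprofiler orfscan --contigs data/contigs.fna --motif ILDxCGVY --out orfs.tsv
head -3 orfs.tsv
```

```
contig	strand	frame	start	end	peptide
g023_contig	+	2	563	676	MFCYMSTQPSYIQDDVNAETSFLEHGSQPILDWCGVY
g023_contig	-	1	250	441	MRPAWNLNPTMAMFKLPCCGHTASCQCRPNMNAYDAPWANDVNAETSSLEHGSQPILDKCGVY
```

All 8 planted precursors (2 per trait-positive genome) are recovered, with
coordinates (1-based, stop codon included) and frame; shuffled-motif decoy
genes are not. A SIMBAL map for a dependent-family probe
(`phyloprofiler simbal --probe ... --family ... --profile ... --out grid.tsv`)
places its hottest windows over the planted diagnostic segment, and
`phyloprofiler discover --config cfg.yaml` chains profile → PPP → SIMBAL →
ORF scan with a run manifest.

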