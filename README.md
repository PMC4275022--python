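# ncecr

Discovery of functional non-coding conserved regions in a gene locus.

Many disease-associated loci exert their effect not through coding
variants but through cis-regulatory elements — enhancers and silencers
scattered through introns and flanking intergenic DNA. A standard route
to finding them is phylogenetic footprinting: screen a locus for
non-coding sequence conserved between distant species, then test each
conserved element in a reporter assay. `ncecr` implements that whole
route as a reusable, tested pipeline for anyone running such a screen:

1. **Conservation screen** (`ncecr.conservation`) — sliding-window
   percent identity over a pairwise alignment and calling of
   evolutionary conserved regions (ECRs) at the established thresholds
   (length > 100 bp, identity > 75%), with location classes and
   U*/In*/D* labels relative to a gene model.
2. **Non-coding filter** (`ncecr.noncoding_filter`) — flags candidates
   that overlap annotated transcripts/ESTs or contain an open reading
   frame longer than 20 amino acids.
3. **Motif scanning** (`ncecr.motif_scan`) — MatInspector-style
   position-weight-matrix scanning with information-weighted matrix and
   core similarity on both strands.
4. **Framework detection** (`ncecr.frameworks`) — ordered sets of ≥ 4
   binding sites present in every species, in the same orientation, with
   inter-site spacing preserved within ±τ nucleotides (τ = 10 or 15),
   intersected with promoter-binding factors.
5. **Reporter statistics** (`ncecr.reporter_stats`) — dual-luciferase
   firefly/Renilla ratios normalized to the promoter-only control,
   pooled two-sample t-tests, and enhancer/silencer/neutral calls.
6. **Synthetic data** (`ncecr.synthetic_data`) — generators for every
   input with known ground truth (implanted conserved blocks, implanted
   motif frameworks, simulated plates), used throughout the test suite.

A thin CLI (`ncecr`) and a five-stage orchestrator with a run manifest
(`ncecr.pipeline`) tie the stages together.

## The statistics in brief

**Window identity.** For a window of W reference residues the identity
is (matching columns) / (columns spanned), so query-side insertions and
gaps inside the span count as mismatches, as in Vista-family profile
scorers. Overlapping qualifying windows merge; merged regions are
trimmed to their outermost conserved residue.

**Matrix similarity.** Each matrix position i carries an information
weight w_i = Σ_b f_ib·log₂(4 f_ib) ∈ [0, 2] bits, and a window x scores

    sim(x) = Σ_i w_i · f_i,x_i / Σ_i w_i · max_b f_ib

so the per-position consensus scores exactly 1. Core similarity is the
same score restricted to the 4 consecutive positions of maximal summed
information (the fast pre-filter).

**Framework validity.** An ordered slot list (TF label, strand) is a
framework if every species has hits occupying the slots in the same
order and orientation, with every adjacent start-to-start spacing within
±τ of the first (reference) species. Only maximal frameworks — not
extendable by any additional site — are reported.

**Reporter calls.** Per well, ratio = firefly/Renilla; ratios are
divided by the mean control ratio of the same experiment. An element's
fold change is the mean normalized ratio; significance comes from a
pooled two-sample Student's t-test against the control wells (df =
n₁+n₂−2), classed enhancer (fold > 1) or silencer (fold < 1) at p < 0.05.

## Worked example

`examples/` holds one short script per capability. Calling conserved
regions on a simulated locus pair with two implanted blocks
(`examples/01_call_conserved_regions.py`):

```
implanted blocks: ['ref:701-880(+)', 'ref:2101-2320(+)']
2 ECR(s) called:
  ref ref:654-901(+)  query query:658-907(+)  identity 0.760  length 248 bp
  ref ref:2135-2350(+)  query query:2144-2359(+)  identity 0.764  length 216 bp
```

Both implants are recovered; the calls extend slightly into background
where flanking windows still clear the 75% threshold, and the reported
identity is recounted over the final region's alignment columns.
Coordinates printed by the package are 1-based inclusive; everything
internal (and all BED output) is 0-based half-open.

Re-analyzing a simulated locus-wide reporter screen
(`examples/05_analyze_reporter_assay.py`, 32 element constructs, 12
carrying true effects) ends with:

```
     I12  12   2.57   1.27e-13  enhancer * 2.50
      D3  12   2.55   8.89e-14  enhancer * 2.50
      D6  12   0.33   1.49e-17  silencer * 0.35
...
12 of 32 elements significant at alpha=0.05 (12 effects implanted)
```

Each line is an element's replicate count, estimated fold change versus
the promoter-only control, t-test p-value and class, next to the fold
the simulator implanted.

The same analyses run from the shell:

```
ncecr ecr scan --alignment pair.maf --gene-model gene.gff3 --out-prefix out/ecrs
ncecr ecr filter --ecrs out/ecrs.tsv --annotations ests.bed --out out/ecrs.nc.tsv
ncecr motif scan --pfm matrices.pfm --fasta species.fasta --out out/hits.tsv
ncecr motif frameworks --hits out/hits.tsv --distance-tolerance 10 --out out/fw.json
ncecr assay analyze --table assay.tsv --out out/results.tsv --plot out/fig.png
ncecr pipeline run --config pipeline.yaml
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions,
numerical choices and known limitations.
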