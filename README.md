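# coevopair

Coevolution-guided contact prediction and restraint generation for a
two-protein complex inferred from metagenome gene adjacency.

The package implements an end-to-end pipeline:

1. **Gene pairing** (`coevopair.pairing`) — pair family-A and family-B gene
   hits found on the same metagenomic contig (optionally requiring the B
   gene immediately downstream on the same strand) and concatenate the two
   family alignments row-wise into a paired alignment.
2. **MSA processing** (`coevopair.msa`) — FASTA/A3M/Stockholm I/O, greedy
   redundancy filtering at an identity ceiling, gap-column filtering,
   identity-neighbour sequence reweighting (Neff), the Nf = Neff/sqrt(L)
   depth statistic, and a cysteine tail census downstream of a
   reference-mapped anchor column.
3. **Coevolution analysis** (`coevopair.coevolution`) — L2-regularized
   pseudolikelihood fitting of a 21-state Potts model on the weighted
   paired alignment, Frobenius-norm coupling scores, average product
   correction (APC), and logistic probability calibration in the normalized
   score and log-depth.
4. **Structure analysis** (`coevopair.structures`) — PDB/mmCIF parsing,
   representative-point (Cβ; Cα for Gly) contact maps, precision@k,
   interdomain contact extraction, the model-fit ratio Rc
   (satisfied contacts over summed prediction probability, native band
   0.7–1.2), minimum cofactor distances, Kabsch superposition, and a
   template-contact-coverage gap score.
5. **Restraint generation** (`coevopair.restraints`) — contact restraints
   (sigmoidal, or bounded centroid-stage), iron–sulfur-cluster coordination
   restraints extracted from a reference ferredoxin structure (Sγ–Sγ
   harmonic distances, Cα-Cβ-Sγ angles, C-Cα-Cβ-Sγ circular-harmonic
   dihedrals), corrinoid-cofactor binding restraints, Rosetta-style
   constraint-file I/O, and rigid cofactor placement by anchor
   superposition.
6. **Synthetic data** (`coevopair.synthetic`) — ground-truthed generators:
   compact toy two-chain folds with known contact maps, Potts models
   planted on those maps, Gibbs-sampled sequence families with controllable
   depth, and synthetic contig sets with adjacent gene pairs plus decoys.
7. **CLI** (`coevopair.cli`) — stage subcommands with a flat YAML config,
   per-stage JSON manifests (input checksums, parameters, version), and
   deterministic outputs per seed.

## CLI

```sh
coevopair simulate --config config.yaml --out run/
coevopair pair     --hits run/gene_hits.tsv --aln-a A.fasta --aln-b B.fasta --out run/
coevopair msa      --aln run/paired.fasta --out run/
coevopair coevolve --aln run/filtered.fasta --weights run/weights.txt \
                   --boundary 30 --out run/
coevopair contacts --preds run/contacts.rr --structure model.pdb --out run/
coevopair restraints --preds run/contacts.rr --out run/
coevopair census   --aln paired.fasta --anchor-id REF --anchor-resnum 73 --out run/
coevopair report   --out run/
```

All stage parameters live in one flat YAML config (see
`coevopair.cli.RunConfig` for keys and defaults); unknown keys are
rejected (exit 3) and missing inputs exit 2.

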