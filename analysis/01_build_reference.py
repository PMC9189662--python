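"""Build the synthetic tRNA reference and serialize it for inspection.

Constructs the bundled toy reference (13 synthetic tRNA genes spanning the
isotypes most often seen among tDRs, two of them identical gene copies, one
intron-carrying, one with a length-75 mature form, two with precursor
flanks, plus 20 synthetic miRNAs and 3 other small ncRNAs), writes the gene
FASTA + annotation table and the derived mature/precursor transcript table
under results/reference/, and reports what was built.
"""

from pathlib import Path

from tdrscape.reference import write_transcript_table
from tdrscape.simulate import toy_reference

OUT = Path(__file__).resolve().parent.parent / "results" / "reference"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = toy_reference(seed=0)

    with open(OUT / "trna_genes.fa", "w") as fa:
        for g in ref.genes:
            fa.write(f">{g.gene_name}\n{g.body_seq}\n")
    with open(OUT / "trna_annotation.tsv", "w") as tsv:
        tsv.write(
            "gene_name\tisotype\tanticodon\tintron_start\tintron_end\tleader_seq\ttrailer_seq\n"
        )
        for g in ref.genes:
            starts = ",".join(str(s) for s, _ in g.intron_intervals)
            ends = ",".join(str(e) for _, e in g.intron_intervals)
            tsv.write(
                f"{g.gene_name}\t{g.isotype}\t{g.anticodon}\t{starts}\t{ends}"
                f"\t{g.leader_seq}\t{g.trailer_seq}\n"
            )
    with open(OUT / "smallrna_annotation.tsv", "w") as tsv:
        tsv.write("name\tkind\tseq\n")
        for s in ref.smallrnas:
            tsv.write(f"{s.name}\t{s.kind}\t{s.seq}\n")

    df = write_transcript_table(ref.transcripts, OUT / "transcripts.tsv")

    print(f"genes: {len(ref.genes)}")
    print(f"mature isodecoders after collapse: {len(ref.mature)}")
    collapsed = [t for t in ref.mature if t.copy_count > 1]
    for t in collapsed:
        print(f"  {t.transcript_name}: {t.copy_count} identical gene copies collapsed")
    print(f"precursor transcripts (with flanks): {len(ref.precursors)}")
    print(f"mature lengths: {sorted(df[df.kind == 'mature']['length'].unique())}")
    print(f"small RNA features: {len(ref.smallrnas)}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
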