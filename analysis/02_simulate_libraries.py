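"""Simulate the stress-response ARM-seq study design with known ground truth.

Generates 2 compartments (cell, Ex) x 2 conditions (control, stress) x 3
replicates, all AlkB-treated, plus one AlkB-untreated control library for
the read-through comparison.  The extracellular profile is dominated by 5'
halves ending at consensus 33 and trimmed 3' halves ending at 74; the
cellular profile by 3' fragments with intact CCA at 76.  Stress shifts a
few fragment populations on the log2 scale, with larger effects in the
extracellular compartment.  FASTQ and ground truth go to scratch/ (they are
regenerated on demand); the sample sheet goes to results/.
"""

from pathlib import Path

from tdrscape.simulate import (
    ConditionProfile,
    SampleSpec,
    cellular_mixture,
    extracellular_mixture,
    simulate_library,
    toy_reference,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "libraries"
RESULTS = ROOT / "results"

SEED = 20260927
N_READS = 4000

# stress effects: log2 shifts of specific fragment populations; extracellular
# effects are larger than cellular ones by design
EX_EFFECTS = {
    ("Glu-CTC-1", "five_prime_half"): 2.0,
    ("Gly-CCC-1", "five_prime_half"): 1.5,
    ("Asp-GTC-2", "three_prime_half_trimmed"): -2.0,
    ("Ser-GCT-1", "three_prime_half_trimmed"): -1.5,
}
CELL_EFFECTS = {
    ("Glu-CTC-1", "three_prime_fragment_intact"): 0.8,
    ("Asp-GTC-2", "three_prime_fragment_intact"): -0.8,
}


def build_samples() -> list[SampleSpec]:
    samples = []
    for compartment, mixture, effects in (
        ("Ex", extracellular_mixture(), EX_EFFECTS),
        ("cell", cellular_mixture(), CELL_EFFECTS),
    ):
        for condition in ("control", "stress"):
            profile = ConditionProfile(
                condition=condition,
                compartment=compartment,
                mixture=mixture,
                effects=effects if condition == "stress" else {},
            )
            for rep in range(1, 4):
                samples.append(
                    SampleSpec(f"{compartment}_{condition}_{rep}", profile, N_READS, alkb=True)
                )
    # one untreated library for the AlkB read-through contrast
    samples.append(
        SampleSpec(
            "cell_control_noalkb",
            ConditionProfile(condition="control", compartment="cell", mixture=cellular_mixture()),
            N_READS,
            alkb=False,
        )
    )
    return samples


def main() -> None:
    if SCRATCH.exists():
        for f in SCRATCH.iterdir():
            f.unlink()
    samples = build_samples()
    reference = toy_reference(seed=0)
    out = simulate_library(SCRATCH, samples, reference, seed=SEED)

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "sample_sheet.tsv", "w") as fh:
        fh.write("sample\tcondition\tcompartment\tgenotype\talkb\n")
        for s in samples:
            fh.write(
                f"{s.sample}\t{s.profile.condition}\t{s.profile.compartment}"
                f"\t{s.profile.genotype}\t{s.alkb}\n"
            )

    truth = out["truth_df"]
    print(f"simulated {len(samples)} libraries, {len(truth)} reads total")
    by_sample = truth.groupby("sample").size()
    print(f"reads per library: min {by_sample.min()}, max {by_sample.max()}")
    trunc = truth.groupby("sample")["truncated"].mean()
    print(
        "RT truncation fraction: AlkB-treated "
        f"{trunc.drop('cell_control_noalkb').mean():.3f}, "
        f"untreated {trunc['cell_control_noalkb']:.3f}"
    )
    print(f"FASTQ + ground truth under {SCRATCH}")
    print(f"sample sheet at {RESULTS / 'sample_sheet.tsv'}")


if __name__ == "__main__":
    main()
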