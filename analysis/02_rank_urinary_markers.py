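"""Stage 2 -- rank candidate urinary markers from tissue profiles.

Summarizes the stage-1 synthetic bank into per-miRNA tissue profiles and
applies the five-term weighted score (over-expression x3, kidney-bladder
and kidney-prostate background terms, minus the kidney and tumour SD
penalties).  Planted over-expressed miRNAs should dominate the top of
the ranking.
"""

from pathlib import Path

from uromir.pipeline import write_tsv
from uromir.prioritize import (
    ScoreWeights,
    breakdowns_to_frame,
    compute_marker_score,
    profiles_from_bank,
    rank_markers,
)
from uromir.simulate import BankSpec, simulate_expression_bank

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 17


def main() -> None:
    bank = simulate_expression_bank(BankSpec(seed=SEED))
    weights = ScoreWeights()  # (3, 1, 1, 2, 1)
    ranked = rank_markers(
        [compute_marker_score(p, weights, "male") for p in profiles_from_bank(bank.matrix)]
    )
    frame = breakdowns_to_frame(ranked)
    write_tsv(frame, RESULTS / "marker_ranking.tsv", {"seed": SEED}, index=False)

    top10 = frame.head(10)
    planted_in_top10 = top10["mirna"].isin(bank.overexpressed).sum()
    print("top 10 candidate urinary markers (male mode):")
    for _, row in top10.iterrows():
        print(f"  {row['mirna']:<12} score {row['score']:6.2f}")
    print(f"{planted_in_top10}/10 of the top 10 are planted over-expressed miRNAs")
    print(f"wrote {RESULTS / 'marker_ranking.tsv'}")


if __name__ == "__main__":
    main()
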