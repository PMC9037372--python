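"""Simulate the study-scale three-cohort plasma exLR dataset.

Generates a 15,000-gene count matrix over 72 CRC / 42 CRA / 80 healthy
samples with 20 planted CRC-upregulated genes, cohort metadata with TNM
stage, CEA status and censored OS/DFS outcomes, and the ground-truth
manifest.  Everything downstream (02-06) reads from results/cohort/.
"""

import json
from pathlib import Path

from exlr.core_data import write_matrix, write_table
from exlr.synthetic_data import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20240917


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    counts, annotation, design, truth = simulate_cohort(cfg)
    write_matrix(counts, OUT / "counts.tsv")
    write_table(annotation, OUT / "annot.tsv")
    write_table(design, OUT / "design.tsv")
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "planted_log2fc": truth.planted_log2fc,
                "hr_per_sd": truth.hr_per_sd,
                "latent_score": truth.latent_score.to_dict(),
                "seed": SEED,
            },
            indent=2,
        )
    )
    n = design["cohort"].value_counts()
    print(
        f"simulated {counts.shape[0]} genes x {counts.shape[1]} samples "
        f"(CRC {n['CRC']}, CRA {n['CRA']}, healthy {n['healthy']}); "
        f"{len(truth.planted_genes)} planted CRC-up genes -> {OUT}"
    )


if __name__ == "__main__":
    main()
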