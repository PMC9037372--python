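"""Frozen-model evaluation on training, validation and clinical subgroups.

Applies the frozen signature model to every cohort: training (LOOCV
scores), held-out validation, and the stage-/CEA-defined subgroups, and
writes one report row per comparison (AUC with DeLong 95% CI, sensitivity,
specificity, accuracy at the frozen threshold).  Nothing is refit here.
"""

from pathlib import Path

import pandas as pd

from exlr.classify_eval import SignatureModel, evaluate, evaluate_subgroups, predict
from exlr.core_data import ExpressionMatrix, read_design, join_design, write_table
from exlr.feature_select import SVMParams, loocv_scores
from exlr.pipeline import DEFAULT_SUBGROUP_PLAN
from exlr.quantify import log2_transform

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240917


def main() -> None:
    tpm = ExpressionMatrix(pd.read_csv(ROOT / "tpm.tsv", sep="\t", index_col=0), "tpm")
    design = read_design(ROOT / "design_split.tsv")
    tpm, design = join_design(tpm, design)
    model = SignatureModel.from_json(ROOT / "model.json")
    log_all = log2_transform(tpm)
    meta = design.set_index("sample_id")

    train_ids = [s for s in tpm.sample_ids if meta.at[s, "split"] == "train"]
    valid_ids = [s for s in tpm.sample_ids if meta.at[s, "split"] == "validation"]
    y_train = meta.loc[train_ids, "cohort"].eq("CRC").to_numpy(dtype=int)
    y_valid = meta.loc[valid_ids, "cohort"].eq("CRC").to_numpy(dtype=int)

    loocv = loocv_scores(log_all.subset_samples(train_ids), y_train, model.features, SVMParams())
    reports = [
        evaluate(loocv, y_train, model.threshold, cohort_name="Training", seed=SEED).to_dict()
    ]
    preds = predict(model, log_all.subset_samples(valid_ids))
    write_table(preds, ROOT / "validation_predictions.tsv")
    reports.append(
        evaluate(
            preds["score"].to_numpy(), y_valid, model.threshold,
            cohort_name="Validation", seed=SEED,
        ).to_dict()
    )
    table = pd.concat(
        [pd.DataFrame(reports), evaluate_subgroups(model, log_all, design, DEFAULT_SUBGROUP_PLAN)],
        ignore_index=True,
    )
    write_table(table, ROOT / "reports.tsv")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
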