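"""Optional: fetch the public TCGA glioma grading table and run the pipeline.

Downloads the preprocessed glioma grading dataset (clinical + mutation
features) from the UCI Machine Learning Repository, converts it to the CSV
schema this package reads, runs the full hybrid selection pipeline, and
prints the achieved accuracy and selected features for qualitative
comparison with published results.  Requires network access; nothing else
in the package depends on it.

Usage:
    python scripts/fetch_tcga_uci.py --seed 0 --out-dir scratch/tcga
"""

from __future__ import annotations

import argparse
import io
import urllib.request
import zipfile
from pathlib import Path

import pandas as pd

UCI_ZIP_URL = (
    "https://archive.ics.uci.edu/static/public/759/"
    "glioma+grading+clinical+and+mutation+features+dataset.zip"
)
# the preprocessed member: Grade 0/1, Gender/Race integer-coded, genes 0/1
PREPROCESSED_MEMBER = "TCGA_InfoWithGrade.csv"


def fetch_preprocessed(out_csv: Path) -> Path:
    print(f"downloading {UCI_ZIP_URL} ...")
    with urllib.request.urlopen(UCI_ZIP_URL, timeout=120) as resp:
        payload = resp.read()
    with zipfile.ZipFile(io.BytesIO(payload)) as zf:
        member = next((m for m in zf.namelist()
                       if m.endswith(PREPROCESSED_MEMBER)), None)
        if member is None:
            raise SystemExit(f"{PREPROCESSED_MEMBER} not found in archive: "
                             f"{zf.namelist()}")
        df = pd.read_csv(zf.open(member))
    # the preprocessed table codes Grade as 0 = LGG, 1 = GBM
    df["Grade"] = df["Grade"].map({0: "LGG", 1: "GBM"})
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    print(f"wrote {len(df)} rows x {df.shape[1] - 1} features to {out_csv}")
    return out_csv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("scratch/tcga"))
    args = parser.parse_args()

    csv = fetch_preprocessed(args.out_dir / "tcga_glioma.csv")

    from gradwise.pipeline import RunConfig, run_gradwise

    config = RunConfig(seed=args.seed, input_path=str(csv),
                       label_column="Grade", positive_label="GBM",
                       out_dir=str(args.out_dir))
    report = run_gradwise(config)
    print(f"\nbest: k={report.best_k} model={report.best_model} "
          f"n_features={len(report.selected_features)} "
          f"acc={report.metrics.acc:.3f}%")
    print("features:", ", ".join(report.selected_features))
    print("\nNote: classifier settings and fold seeds differ from the "
          "published runs, so accuracies are comparable only qualitatively.")


if __name__ == "__main__":
    main()
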