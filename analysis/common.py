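"""Shared paths for the numbered analysis drivers.

Bulky regenerable intermediates (raw panel, z-panel) live under
``scratch/`` — they are rebuilt by rerunning the drivers — while the
small summary tables each step reports land under ``results/analysis``.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"

COHORT_DIR = SCRATCH / "cohort"
ZPANEL_CSV = COHORT_DIR / "zpanel.csv"
RAW_CSV = COHORT_DIR / "raw_panel.csv"
CHARTS_CSV = COHORT_DIR / "charts.csv"
LABELS_CSV = COHORT_DIR / "true_labels.csv"

SEED = 0
N_SUBJECTS = 1143


def ensure_dirs() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise SystemExit(f"{path} missing - run {producer} first")
    return path
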