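"""CSV/TSV readers and writers for matrices, labels and results.

Matrix files: first column = sample ID, header row = feature names,
remaining cells numeric. Label files: two columns (sample_id, label).
Delimiter is auto-detected from the extension (.tsv / .tab -> tab).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import DiagnosisVector, ModalityMatrix, ValidationError
from .factorization import FactorizationResult

__all__ = [
    "read_modality_matrix",
    "read_labels",
    "write_modality_matrix",
    "write_result",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_modality_matrix(path: str | Path, modality_tag: str = "") -> ModalityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(f"{path}: missing values are not supported")
    return ModalityMatrix(
        values,
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
        modality_tag or path.stem,
    )


def read_labels(path: str | Path) -> DiagnosisVector:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns (sample_id, label)")
    return DiagnosisVector(df.iloc[:, 1].to_numpy(dtype=int), [str(s) for s in df.iloc[:, 0]])


def write_modality_matrix(x: ModalityMatrix, path: str | Path) -> None:
    path = Path(path)
    x.to_frame().to_csv(path, sep=_sep(path), index_label="sample_id")


def write_result(result: FactorizationResult, out_dir: str | Path, extra_meta: dict | None = None) -> None:
    """Write W/H1/H2, the per-iteration traces and a run-metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result.W).to_csv(out / "W.csv", index_label="sample")
    pd.DataFrame(result.H1).to_csv(out / "H1.csv", index_label="module")
    pd.DataFrame(result.H2).to_csv(out / "H2.csv", index_label="module")
    trace = pd.DataFrame(
        {
            "objective": result.objective_trace,
            "relative_error": result.relative_error_trace,
            **{k: v for k, v in result.component_traces.items()},
        }
    )
    trace.to_csv(out / "trace.csv", index_label="iteration")
    meta = {
        "converged": result.converged,
        "n_iter": result.n_iter,
        "params": None if result.params is None else vars(result.params),
    }
    if extra_meta:
        meta.update(extra_meta)
    (out / "run.json").write_text(json.dumps(meta, indent=2, default=str))
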