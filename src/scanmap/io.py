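"""Plain-text interchange: TSV matrices/maps and JSON descriptors."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import TaskDesign
from .synthetic import BoldRun, CorticalStrip, StructuralMaps

__all__ = [
    "write_bold_run",
    "read_bold_run",
    "write_strip",
    "read_strip",
    "write_matrix",
    "read_matrix",
    "write_table",
    "write_design",
    "read_design",
    "write_structural_maps",
]


def write_bold_run(run: BoldRun, path: str | Path) -> None:
    """Vertices x frames TSV plus a JSON sidecar {tr, run_type}."""
    path = Path(path)
    pd.DataFrame(run.data).to_csv(path, sep="\t", header=False, index=False, float_format="%.8g")
    sidecar = {"tr": run.tr, "run_type": run.run_type}
    if run.design is not None:
        sidecar["design"] = run.design.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_bold_run(path: str | Path) -> BoldRun:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    design = TaskDesign.from_dict(meta["design"]) if "design" in meta else None
    return BoldRun(data=data, tr=meta["tr"], run_type=meta["run_type"], design=design)


def write_strip(strip: CorticalStrip, path: str | Path) -> None:
    Path(path).write_text(json.dumps(strip.to_dict()))


def read_strip(path: str | Path) -> CorticalStrip:
    return CorticalStrip.from_dict(json.loads(Path(path).read_text()))


def write_matrix(arr: np.ndarray, path: str | Path, labels: list[str] | None = None) -> None:
    """Square matrix TSV with an id header row/column when labels given."""
    if labels is not None:
        pd.DataFrame(arr, index=labels, columns=labels).to_csv(path, sep="\t", float_format="%.8g")
    else:
        pd.DataFrame(arr).to_csv(path, sep="\t", header=False, index=False, float_format="%.8g")


def read_matrix(path: str | Path, labelled: bool = False) -> pd.DataFrame:
    if labelled:
        return pd.read_csv(path, sep="\t", index_col=0)
    return pd.read_csv(path, sep="\t", header=None)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_design(design: TaskDesign, path: str | Path) -> None:
    Path(path).write_text(json.dumps(design.to_dict(), indent=1))


def read_design(path: str | Path) -> TaskDesign:
    return TaskDesign.from_dict(json.loads(Path(path).read_text()))


def write_structural_maps(maps: StructuralMaps, path: str | Path) -> None:
    pd.DataFrame(
        {
            "thickness": maps.thickness,
            "fa": maps.fa,
            "myelin": maps.myelin,
            "myelin_raw": maps.myelin_raw,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
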