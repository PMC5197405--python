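"""File formats and configuration.

Trial tables are plain CSV, one row per presentation, with spike times
stored as semicolon-joined ms values at 0.1-ms precision — inspectable with
any spreadsheet and loss-free for 1-ms-bin analysis.  Configuration is YAML
mirroring :class:`PipelineConfig`, whose defaults are the study's printed
constants (patch fading k = 1.8, count window 40–300 ms, alpha = 0.01,
Lowess span 0.12).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from borderown.simulate import TRIAL_MS, CellDataset

TRIAL_COLUMNS = [
    "cell_id",
    "test",
    "scene_id",
    "size_deg",
    "side",
    "polarity",
    "extent",
    "rep",
    "spike_times",
]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults are the study constants."""

    seed: int = 0
    n_cells: int = 30
    n_scenes: int = 10
    preset: str = "paper_calibrated"
    patch_fade_k: float = 1.8
    count_window: tuple = (40.0, 300.0)
    alpha: float = 0.01
    bootstrap_B: int = 200
    n_surrogates: int = 500
    lowess_span: float = 0.12
    min_omi: float = 0.20
    trials_path: str | None = None
    out_path: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["count_window"] = list(self.count_window)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "count_window" in data:
            data["count_window"] = tuple(data["count_window"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def write_trials(cells, path) -> None:
    """Write a list of cells as a trial-table CSV (0.1-ms spike times)."""
    rows = []
    for cell in cells:
        for i, row in cell.trials.iterrows():
            times = ";".join(f"{t:.1f}" for t in cell.spike_times(i))
            rows.append(
                [
                    cell.cell_id,
                    row["test"],
                    row["scene_id"],
                    "" if pd.isna(row["size_deg"]) else row["size_deg"],
                    row["side"],
                    row["polarity"],
                    row["extent"],
                    row["rep"],
                    times,
                ]
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path) -> list[CellDataset]:
    """Read a trial-table CSV into per-cell datasets.

    An empty file yields an empty list; a malformed row raises with its CSV
    line number.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, dtype={"spike_times": str, "scene_id": str}, keep_default_na=False)
    if len(df) == 0:
        return []
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    cells = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        n = len(sub)
        spikes = np.zeros((n, TRIAL_MS), dtype=bool)
        trials = []
        for k, (idx, row) in enumerate(sub.iterrows()):
            line_no = idx + 2  # header + 1-based
            try:
                size = float(row["size_deg"]) if row["size_deg"] != "" else np.nan
                rep = int(row["rep"])
                raw = row["spike_times"]
                if raw:
                    times = np.array([float(x) for x in raw.split(";")])
                    if ((times < 0) | (times >= TRIAL_MS)).any():
                        raise ValueError("spike time outside [0, 300) ms")
                    spikes[k, times.astype(int)] = True
                trials.append(
                    (row["test"], row["scene_id"], size, row["side"], row["polarity"], row["extent"], rep)
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"malformed trial row at line {line_no}: {exc}") from exc
        frame = pd.DataFrame(
            trials,
            columns=["test", "scene_id", "size_deg", "side", "polarity", "extent", "rep"],
        )
        cells.append(CellDataset(cell_id=str(cell_id), trials=frame, spikes=spikes))
    return cells


def effects_table(effects) -> pd.DataFrame:
    """Per-cell effect estimates as a flat table (CSV-ready)."""
    rows = []
    for e in effects:
        rows.append(
            {
                "cell_id": e.cell_id,
                "square": e.square,
                "full": e.full,
                "patch": e.patch,
                "context": e.context,
                "square_norm": e.square_norm,
                "full_norm": e.full_norm,
                "patch_norm": e.patch_norm,
                "context_norm": e.context_norm,
                "se_square": e.se_square,
                "se_full": e.se_full,
                "se_patch": e.se_patch,
                "se_context": e.se_context,
                "p_square": e.p_square,
                "p_full": e.p_full,
                "p_patch": e.p_patch,
                "p_context": e.p_context,
                "preferred_side": e.preferred_side,
            }
        )
    return pd.DataFrame(rows)
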