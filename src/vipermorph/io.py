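"""TPS landmark files, curve specifications and specimen metadata.

The entry point of the pipeline is a pair of TPS files (one per view,
tpsDIG2 dialect), a metadata CSV with columns ``id,group`` (optionally
``sex,stage``) and a JSON curve specification naming, per view, which
landmarks are sliding semilandmarks and how they chain into curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "SpecimenRecord",
    "CurveSpec",
    "TpsParseError",
    "read_tps",
    "write_tps",
    "read_curve_spec",
    "read_metadata",
    "assemble_dataset",
]

#: default landmark counts per view
VIEW_LANDMARK_COUNTS = {"dorsal": 33, "lateral": 50}


class TpsParseError(ValueError):
    """Raised when a TPS record is malformed."""


@dataclass
class CurveSpec:
    """Semilandmark curves for one view.

    ``curves`` is a list of ordered landmark-index lists (0-based).  Every
    index that is interior to a curve (has both a predecessor and a
    successor along it) is a sliding semilandmark; curve endpoints are
    treated as fixed anchors.
    """

    view: str
    n_landmarks: int
    curves: list[list[int]] = field(default_factory=list)

    def landmark_kind(self) -> np.ndarray:
        kind = np.full(self.n_landmarks, "fixed", dtype=object)
        for c in self.curves:
            for i in c[1:-1]:
                kind[i] = "semi"
        return kind

    def validate(self) -> None:
        seen_semi: set[int] = set()
        for c in self.curves:
            if len(c) < 3:
                raise ValueError(
                    f"curve {c} in view {self.view!r} has no interior "
                    "(sliding) landmarks; curves need at least 3 points"
                )
            if any(i < 0 or i >= self.n_landmarks for i in c):
                raise ValueError(f"curve index out of range in view {self.view!r}")
            interior = set(c[1:-1])
            if interior & seen_semi:
                raise ValueError(
                    f"semilandmark shared between curves in view {self.view!r}"
                )
            seen_semi |= interior


@dataclass
class LandmarkConfiguration:
    """One view's raw landmark configuration (image units)."""

    coords: np.ndarray  # (p, 2)
    landmark_kind: np.ndarray  # (p,) in {"fixed", "semi"}
    curves: list[list[int]]
    view: str
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a p x 2 matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite landmark coordinates")
        if len(self.landmark_kind) != self.n_landmarks:
            raise ValueError("landmark_kind length mismatch")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def semi_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.landmark_kind) == "semi")

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.coords.copy(),
            np.asarray(self.landmark_kind).copy(),
            [list(c) for c in self.curves],
            self.view,
            self.scale,
        )


@dataclass
class SpecimenRecord:
    """A specimen: id, taxonomic/biological labels and both views."""

    id: str
    group: str
    sex: str | None
    stage: str | None
    dorsal: LandmarkConfiguration
    lateral: LandmarkConfiguration


def _finish_record(
    rec_no: int,
    lm_declared: int | None,
    coords: list[list[float]],
    rec_id: str | None,
    image: str | None,
    scale: float | None,
    curve_spec: CurveSpec,
    view: str,
) -> tuple[LandmarkConfiguration, str]:
    if lm_declared is None:
        raise TpsParseError(f"record {rec_no}: no LM= line")
    if len(coords) != lm_declared:
        raise TpsParseError(
            f"record {rec_no} (id={rec_id or image or '?'}): LM={lm_declared} "
            f"but {len(coords)} coordinate lines found"
        )
    if lm_declared != curve_spec.n_landmarks:
        raise ValueError(
            f"record {rec_no}: {lm_declared} landmarks but view {view!r} "
            f"expects {curve_spec.n_landmarks}"
        )
    config = LandmarkConfiguration(
        np.array(coords, dtype=float),
        curve_spec.landmark_kind(),
        [list(c) for c in curve_spec.curves],
        view,
        scale,
    )
    ident = rec_id if rec_id is not None else (image if image is not None else str(rec_no))
    return config, ident


def read_tps(
    path: str | Path, view: str, curve_spec: CurveSpec
) -> tuple[list[LandmarkConfiguration], list[str]]:
    """Read a tpsDIG-dialect TPS file.

    Each record is ``LM=<p>`` followed by ``p`` "x y" lines; optional
    ``CURVES=``/``POINTS=`` blocks contribute additional coordinate lines
    (appended after the LM block, as tpsDIG writes outline points);
    ``ID=`` (fallback ``IMAGE=``, fallback record ordinal) names the
    specimen.  ``SCALE=`` is retained as metadata only — Procrustes
    superimposition removes scale.
    """
    curve_spec.validate()
    configs: list[LandmarkConfiguration] = []
    ids: list[str] = []
    lm_declared: int | None = None
    coords: list[list[float]] = []
    rec_id: str | None = None
    image: str | None = None
    scale: float | None = None
    rec_no = 0

    def flush() -> None:
        nonlocal lm_declared, coords, rec_id, image, scale
        if lm_declared is None and not coords:
            return
        config, ident = _finish_record(
            rec_no, lm_declared, coords, rec_id, image, scale, curve_spec, view
        )
        configs.append(config)
        ids.append(ident)
        lm_declared, coords, rec_id, image, scale = None, [], None, None, None

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key_u = key.strip().upper()
        if key_u == "LM":
            flush()
            rec_no += 1
            try:
                lm_declared = int(value.strip())
            except ValueError as exc:
                raise TpsParseError(f"record {rec_no}: bad LM= line {line!r}") from exc
        elif key_u in ("CURVES", "POINTS"):
            continue  # coordinate lines that follow are appended below
        elif key_u == "ID":
            rec_id = value.strip()
        elif key_u == "IMAGE":
            image = value.strip()
        elif key_u == "SCALE":
            scale = float(value.strip())
        elif key_u in ("COMMENT", "VARIABLES", "RADII"):
            continue
        else:
            parts = line.split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise TpsParseError(
                    f"record {rec_no}: unparseable line {line!r}"
                ) from exc
            coords.append([x, y])
    flush()
    return configs, ids


def write_tps(
    path: str | Path,
    configs: Sequence[LandmarkConfiguration],
    ids: Sequence[str],
) -> None:
    """Write configurations in the TPS dialect :func:`read_tps` accepts."""
    lines: list[str] = []
    for config, ident in zip(configs, ids):
        lines.append(f"LM={config.n_landmarks}")
        for x, y in config.coords:
            lines.append(f"{float(x)!r} {float(y)!r}")
        lines.append(f"ID={ident}")
        if config.scale is not None:
            lines.append(f"SCALE={float(config.scale)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve_spec(path: str | Path) -> dict[str, CurveSpec]:
    """Read a JSON curve specification.

    Layout: ``{"dorsal": {"n_landmarks": 33, "curves": [[0,1,...], ...]},
    "lateral": {...}}`` with 0-based landmark indices.
    """
    raw = json.loads(Path(path).read_text())
    out = {}
    for view, entry in raw.items():
        spec = CurveSpec(view, int(entry["n_landmarks"]), [list(map(int, c)) for c in entry.get("curves", [])])
        spec.validate()
        out[view] = spec
    return out


def write_curve_spec(path: str | Path, specs: dict[str, CurveSpec]) -> None:
    payload = {
        view: {"n_landmarks": s.n_landmarks, "curves": s.curves}
        for view, s in specs.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata CSV (required columns ``id,group``)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing required columns: {sorted(missing)}")
    for col in ("sex", "stage"):
        if col not in df.columns:
            df[col] = pd.NA
    return df[["id", "group", "sex", "stage"]]


def assemble_dataset(
    dorsal: tuple[list[LandmarkConfiguration], list[str]],
    lateral: tuple[list[LandmarkConfiguration], list[str]],
    metadata: pd.DataFrame,
) -> tuple[list[SpecimenRecord], dict[str, int]]:
    """Inner-join both views with metadata on specimen id.

    Returns the joined records plus a per-reason count of dropped ids.
    Specimens without a taxonomic (group) assignment are excluded, as are
    ids missing either view or the metadata row.  Zero joined records is
    an error.
    """
    d_configs, d_ids = dorsal
    l_configs, l_ids = lateral
    d_map = dict(zip(d_ids, d_configs))
    l_map = dict(zip(l_ids, l_configs))
    meta = metadata.set_index("id")

    dropped = {
        "missing dorsal": 0,
        "missing lateral": 0,
        "missing metadata": 0,
        "no taxonomic assignment": 0,
    }
    all_ids = list(dict.fromkeys([*d_ids, *l_ids, *meta.index.tolist()]))
    records: list[SpecimenRecord] = []
    for ident in all_ids:
        if ident not in d_map:
            dropped["missing dorsal"] += 1
            continue
        if ident not in l_map:
            dropped["missing lateral"] += 1
            continue
        if ident not in meta.index:
            dropped["missing metadata"] += 1
            continue
        row = meta.loc[ident]
        group = row["group"]
        if pd.isna(group) or str(group).strip() == "":
            dropped["no taxonomic assignment"] += 1
            continue
        sex = None if pd.isna(row["sex"]) else str(row["sex"])
        stage = None if pd.isna(row["stage"]) else str(row["stage"])
        records.append(
            SpecimenRecord(str(ident), str(group), sex, stage, d_map[ident], l_map[ident])
        )
    if not records:
        raise ValueError("no specimens survived the id join across views and metadata")
    return records, dropped
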