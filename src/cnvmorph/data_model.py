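"""Shared data types and table IO for ROI-level morphometry cohorts.

A cohort is a flat table with one row per subject: identifiers, genotype
group, ascertainment, scanning site, covariates (age, sex, total
intracranial volume, total grey matter), then one column per ROI.  ROI
columns are prefixed ``roi_`` and their order is significant: it is shared
with :class:`RoiAtlas` and every effect map derived from the table.

Volumes are litre-scale; surface metrics keep their native units.  A table
never mixes metric types.  Sex is coded 0/1 with the reference level
recorded in :data:`SEX_REFERENCE`.  Missing values in covariates used by a
model are a hard error - subjects failing QC are excluded upstream, never
imputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LOCI = ("1q21.1", "16p11.2", "22q11.2", "15q11.2")
COPY_STATES = ("del", "dup")
CONTROL_GROUP = "control"
MANDATORY_COLUMNS = (
    "subject_id",
    "group",
    "ascertainment",
    "site",
    "age",
    "sex",
    "TIV",
    "total_GM",
)
ROI_PREFIX = "roi_"
SEX_REFERENCE = 0  # sex==0 is the reference level of the 0/1 coding


class SchemaError(ValueError):
    """A table is missing a mandatory column or has a malformed header."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names row and column."""


class ValidationError(ValueError):
    """Contents violate a documented invariant."""


def parse_group(label: str) -> tuple[str, str]:
    """Split a genotype label into (locus, copy state).

    ``"16p11.2_del" -> ("16p11.2", "del")``; the control label maps to
    ``("control", "none")``.
    """
    if label == CONTROL_GROUP:
        return (CONTROL_GROUP, "none")
    locus, _, copy = label.rpartition("_")
    if not locus or copy not in COPY_STATES:
        raise ValidationError(
            f"genotype label {label!r} is not 'control' or '<locus>_<del|dup>'"
        )
    return locus, copy


@dataclass
class CohortTable:
    """Per-subject genotype, covariates, site, global metrics and ROI values.

    Parameters
    ----------
    data:
        Flat DataFrame holding the mandatory columns, optional ``diagnosis``
        (semicolon-joined flag set) and ``family_id`` columns, and ROI
        columns prefixed ``roi_``.
    metric:
        Label of the morphometry metric the ROI columns carry
        (e.g. ``"GM_volume"``, ``"surface_area"``, ``"cortical_thickness"``).
    """

    data: pd.DataFrame
    metric: str = "GM_volume"

    def __post_init__(self) -> None:
        self.validate()

    # -- views ---------------------------------------------------------
    @property
    def roi_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(ROI_PREFIX)]

    @property
    def roi_ids(self) -> list[str]:
        return [c[len(ROI_PREFIX):] for c in self.roi_columns]

    @property
    def n_roi(self) -> int:
        return len(self.roi_columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def roi_values(self) -> np.ndarray:
        """(n_subjects, n_roi) float array in stored column order."""
        return self.data[self.roi_columns].to_numpy(dtype=float)

    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.data.loc[mask].reset_index(drop=True), self.metric)

    def diagnosis_sets(self) -> list[set[str]]:
        """Per-subject sets of diagnosis flags (empty when column absent)."""
        if "diagnosis" not in self.data.columns:
            return [set() for _ in range(len(self.data))]
        out = []
        for cell in self.data["diagnosis"].fillna(""):
            cell = str(cell).strip()
            out.append(set(cell.split(";")) - {""} if cell else set())
        return out

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table missing mandatory column(s): {missing}")
        if not self.roi_columns:
            raise SchemaError(f"cohort table has no '{ROI_PREFIX}*' columns")
        dup = self.data["subject_id"][self.data["subject_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate subject_id(s): {sorted(set(dup))}")
        for col in ("age", "sex", "TIV", "total_GM"):
            vals = pd.to_numeric(self.data[col], errors="coerce")
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna())[0])
                raise ParseError(
                    f"non-numeric or missing value in column {col!r} at row {row}"
                )
        for label in self.data["group"].unique():
            parse_group(label)  # raises on malformed labels
        bad_sex = set(self.data["sex"].unique()) - {0, 1}
        if bad_sex:
            raise ValidationError(f"sex must be coded 0/1, found {sorted(bad_sex)}")


def read_cohort(path: str | Path, dialect: str = "tsv") -> CohortTable:
    """Read a cohort table from TSV or CSV.

    ROI cells must be numeric; the first offending cell is reported with
    its row index and column name.  ROI column order is preserved exactly.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "site": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s): {missing}")
    roi_cols = [c for c in df.columns if c.startswith(ROI_PREFIX)]
    if not roi_cols:
        raise SchemaError(f"{path.name}: no '{ROI_PREFIX}*' columns")
    for col in roi_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ParseError(
                f"{path.name}: cannot parse cell at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = vals
    return CohortTable(df)


def write_cohort(table: CohortTable, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    table.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ROI atlas


@dataclass
class RoiAtlas:
    """ROI names, hemisphere labels, and unit-sphere centroid coordinates.

    Midline ROIs (no spherical embedding on either hemisphere's sphere)
    are permitted; they are held fixed by spin permutations.
    """

    roi_ids: list[str]
    hemisphere: list[str]  # each in {"L", "R", "midline"}
    centroids: np.ndarray  # (R, 3), unit-norm rows

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.roi_ids) != len(set(self.roi_ids)):
            raise ValidationError("roi_ids must be unique")
        if self.centroids.shape != (len(self.roi_ids), 3):
            raise ValidationError("centroids must be (R, 3)")
        bad = set(self.hemisphere) - {"L", "R", "midline"}
        if bad:
            raise ValidationError(f"unknown hemisphere label(s): {sorted(bad)}")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("centroids must have unit norm within 1e-9")

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)

    def hashable_repr(self) -> str:
        rows = [
            f"{rid}\t{hemi}\t{c[0]:.12f}\t{c[1]:.12f}\t{c[2]:.12f}"
            for rid, hemi, c in zip(self.roi_ids, self.hemisphere, self.centroids)
        ]
        return "\n".join(rows)


def read_roi_atlas(path: str | Path) -> RoiAtlas:
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str})
    needed = {"roi_id", "hemisphere", "x", "y", "z"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"atlas file missing column(s): {sorted(missing)}")
    return RoiAtlas(
        roi_ids=df["roi_id"].tolist(),
        hemisphere=df["hemisphere"].tolist(),
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_roi_atlas(atlas: RoiAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "roi_id": atlas.roi_ids,
            "hemisphere": atlas.hemisphere,
            "x": atlas.centroids[:, 0],
            "y": atlas.centroids[:, 1],
            "z": atlas.centroids[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Effect maps


@dataclass
class EffectMap:
    """Per-ROI Cohen's d (and t, df, group sizes) for one case-control contrast."""

    contrast_id: str
    roi_ids: list[str]
    d: np.ndarray
    t: np.ndarray
    df: int
    n_case: int
    n_control: int
    covariate_set: list[str] = field(default_factory=list)
    # sampling variance of each d value implied by the fitted design,
    # (X'X)^-1[group,group] * df/(df-2); falls back to the two-sample
    # approximation (1/n1 + 1/n2) * df/(df-2) when absent
    d_var_scale: float | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.validate()

    def validate(self) -> None:
        R = len(self.roi_ids)
        if self.d.shape != (R,) or self.t.shape != (R,):
            raise ValidationError(
                f"effect map {self.contrast_id!r}: d/t length must equal ROI count {R}"
            )
        if not (np.all(np.isfinite(self.d)) and np.all(np.isfinite(self.t))):
            raise ValidationError(f"effect map {self.contrast_id!r}: non-finite values")
        if np.any(np.sign(self.d) * np.sign(self.t) < 0):
            raise ValidationError(
                f"effect map {self.contrast_id!r}: d and t disagree in sign"
            )
        if self.df <= 0:
            raise ValidationError(f"effect map {self.contrast_id!r}: df must be > 0")

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)


def write_effect_map(emap: EffectMap, path: str | Path) -> None:
    """Write an effect map as TSV (roi_id, d, t) plus a JSON sidecar.

    The sidecar ``<path>.json`` carries contrast id, df, group sizes and
    the covariate set; numeric columns round-trip within 1e-12.
    """
    path = Path(path)
    pd.DataFrame({"roi_id": emap.roi_ids, "d": emap.d, "t": emap.t}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    sidecar = {
        "contrast_id": emap.contrast_id,
        "df": int(emap.df),
        "n_case": int(emap.n_case),
        "n_control": int(emap.n_control),
        "covariate_set": list(emap.covariate_set),
        "d_var_scale": emap.d_var_scale,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_effect_map(path: str | Path, atlas: RoiAtlas | None = None) -> EffectMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str})
    missing = {"roi_id", "d", "t"} - set(df.columns)
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {sorted(missing)}")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ParseError(f"missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    emap = EffectMap(
        contrast_id=meta["contrast_id"],
        roi_ids=df["roi_id"].tolist(),
        d=df["d"].to_numpy(dtype=float),
        t=df["t"].to_numpy(dtype=float),
        df=meta["df"],
        n_case=meta["n_case"],
        n_control=meta["n_control"],
        covariate_set=meta["covariate_set"],
        d_var_scale=meta.get("d_var_scale"),
    )
    if atlas is not None and emap.roi_ids != atlas.roi_ids:
        raise ValidationError(
            f"{path.name}: ROI ids do not match the atlas "
            f"({emap.n_roi} vs {atlas.n_roi} ROIs)"
        )
    return emap


# ---------------------------------------------------------------------------
# Cohort filtering (sensitivity analyses)

FILTER_NAMES = ("exclude_diagnosed", "ascertainment", "site", "group_in")


def filter_cohort(table: CohortTable, **predicates) -> CohortTable:
    """Subset a cohort by named predicates.

    Supported predicates: ``exclude_diagnosed=True`` (drop any subject with
    a nonempty diagnosis flag set), ``ascertainment="clinical"``,
    ``site="S1"``, ``group_in=[...]``.  Independent predicates commute and
    each is idempotent.  An empty result is allowed but raises a warning.
    """
    unknown = set(predicates) - set(FILTER_NAMES)
    if unknown:
        raise ValueError(
            f"unknown filter(s) {sorted(unknown)}; supported: {FILTER_NAMES}"
        )
    mask = np.ones(table.n_subjects, dtype=bool)
    if predicates.get("exclude_diagnosed"):
        flags = table.diagnosis_sets()
        mask &= np.array([len(s) == 0 for s in flags])
    if "ascertainment" in predicates:
        mask &= (table.data["ascertainment"] == predicates["ascertainment"]).to_numpy()
    if "site" in predicates:
        mask &= (table.data["site"] == str(predicates["site"])).to_numpy()
    if "group_in" in predicates:
        allowed = set(predicates["group_in"])
        mask &= table.data["group"].isin(allowed).to_numpy()
    if not mask.any():
        warnings.warn("filter_cohort produced an empty table", UserWarning)
    return table.subset(mask)
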