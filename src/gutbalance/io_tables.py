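"""Tabular I/O and the package's core containers.

Consumes MetaPhlAn-merged-style taxonomic tables and HUMAnN-pathabundance-style
functional tables (tab-separated, features in rows, samples in columns), plus a
per-sample clinical/metadata table and an optional oxygen-tolerance annotation
map.  Everything is held internally as pandas objects; compositions are always
closed to unit sum (``unit_scale='fraction'``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLOSURE_ATOL = 1e-6

#: clinical columns that must always be present
REQUIRED_CLINICAL = ("patient_id", "timepoint")

#: canonical CPET / lung-function parameter names
CPET_PARAMETERS = (
    "FEV1%", "TLC%", "RV%", "sGaw%", "Watt", "VE", "VO2",
    "O2/HR", "VE/VCO2", "VE/VO2",
)


class TableError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """A samples x features relative-abundance matrix.

    ``values`` rows are compositions: non-negative, summing to 1 after
    :meth:`close`.  Feature ids may be bare names or pipe-separated lineage
    strings (``k__...|p__...|...|s__Species_name``).
    """

    values: pd.DataFrame  # samples x features
    unit_scale: str = "fraction"

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise TableError("empty abundance table")
        if self.values.index.duplicated().any():
            raise TableError("duplicate sample ids")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise TableError(f"duplicate feature ids: {list(dups)[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise TableError("negative abundance value")
        if not np.isfinite(arr).all():
            raise TableError("non-finite abundance value")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- closure ---------------------------------------------------------
    def is_closed(self, atol: float = CLOSURE_ATOL) -> bool:
        target = 1.0 if self.unit_scale == "fraction" else 100.0
        sums = self.values.sum(axis=1).to_numpy()
        return bool(np.allclose(sums, target, atol=atol))

    def close(self) -> "AbundanceTable":
        """Renormalise each row to sum 1 (idempotent); unit_scale -> fraction."""
        sums = self.values.sum(axis=1)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise TableError(f"all-zero sample rows: {bad[:5]}")
        if self.unit_scale == "fraction" and np.allclose(sums, 1.0, atol=1e-12):
            return AbundanceTable(self.values, unit_scale="fraction")
        closed = self.values.div(sums, axis=0)
        return AbundanceTable(closed, unit_scale="fraction")

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise TableError(f"unknown sample ids: {sorted(missing)[:5]}")
        return AbundanceTable(self.values.loc[ids], unit_scale=self.unit_scale)

    def subset_features(self, feature_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(feature_ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise TableError(f"unknown feature ids: {sorted(missing)[:5]}")
        return AbundanceTable(self.values[ids], unit_scale=self.unit_scale)

    def pseudo_fraction(self) -> float:
        """Half the smallest nonzero value; the table-wide zero replacement."""
        arr = self.matrix()
        nz = arr[arr > 0]
        if nz.size == 0:
            raise TableError("table has no nonzero values")
        return float(nz.min()) / 2.0


@dataclass
class ClinicalTable:
    """Per-sample clinical metadata: covariates, outcomes and CPET parameters."""

    data: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        for col in REQUIRED_CLINICAL:
            if col not in self.data.columns:
                raise TableError(f"clinical table missing required column {col!r}")
        bad_tp = set(self.data["timepoint"].dropna()) - {"pre", "post"}
        if bad_tp:
            raise TableError(f"timepoint values outside {{pre, post}}: {sorted(bad_tp)}")
        dup = self.data.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            raise TableError("a patient has more than one row per timepoint")
        for col in ("COPD", "recurrence"):
            if col in self.data.columns:
                vals = set(pd.to_numeric(self.data[col], errors="coerce").dropna())
                if not vals <= {0, 1, 0.0, 1.0}:
                    raise TableError(f"binary column {col!r} not coded 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def patients(self) -> list[str]:
        return sorted(self.data["patient_id"].unique())

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise TableError(f"unknown clinical column {name!r}")
        return self.data[name]

    def per_patient(self, columns: Iterable[str]) -> pd.DataFrame:
        """Patient-level view (values constant within patient, first row wins)."""
        cols = list(columns)
        for c in cols:
            if c not in self.data.columns:
                raise TableError(f"unknown clinical column {c!r}")
        return (
            self.data.sort_values("timepoint")
            .groupby("patient_id")[cols]
            .first()
            .sort_index()
        )


@dataclass
class PairedDesign:
    """patient -> (pre sample, post sample), one pair per patient."""

    pairs: list[tuple[str, str, str]]  # (patient_id, pre_sample, post_sample)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for patient, pre, post in self.pairs:
            if pre == post:
                raise TableError(f"patient {patient}: pre == post sample id")
            for sid in (pre, post):
                if sid in seen:
                    raise TableError(f"sample {sid} appears in more than one pair")
                seen.add(sid)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def patient_ids(self) -> list[str]:
        return [p for p, _, _ in self.pairs]

    @property
    def pre_samples(self) -> list[str]:
        return [pre for _, pre, _ in self.pairs]

    @property
    def post_samples(self) -> list[str]:
        return [post for _, _, post in self.pairs]

    def subset(self, patients: Iterable[str]) -> "PairedDesign":
        keep = set(patients)
        sub = [t for t in self.pairs if t[0] in keep]
        if not sub:
            raise TableError("no pairs left after subsetting")
        return PairedDesign(sub)


@dataclass
class OxygenAnnotation:
    """feature id -> oxygen-tolerance class (aerobe / anaerobe / unknown)."""

    classes: dict[str, str] = field(default_factory=dict)

    VALID = ("aerobe", "anaerobe", "unknown")

    def __post_init__(self) -> None:
        bad = {v for v in self.classes.values()} - set(self.VALID)
        if bad:
            raise TableError(f"unknown oxygen classes: {sorted(bad)}")

    def lookup(self, feature_id: str) -> str:
        """Match on the terminal species token, rank prefixes stripped."""
        key = species_token(feature_id)
        return self.classes.get(key, self.classes.get(feature_id, "unknown"))

    def features_of(self, table: AbundanceTable, cls: str) -> list[str]:
        if cls not in self.VALID:
            raise TableError(f"unknown oxygen class {cls!r}")
        hits = [f for f in table.feature_ids if self.lookup(f) == cls]
        return hits


# ---------------------------------------------------------------------------
# lineage helpers

_RANK_RE = re.compile(r"^[a-z]__")


def lineage_ranks(feature_id: str) -> dict[str, str]:
    """Parse ``k__Bacteria|p__Firmicutes|...`` into {rank letter: name}."""
    ranks: dict[str, str] = {}
    for token in feature_id.split("|"):
        if len(token) > 3 and token[1:3] == "__" and token[0].isalpha():
            ranks[token[0]] = token[3:]
    return ranks


def species_token(feature_id: str) -> str:
    """Terminal species token with rank prefix stripped; the match key."""
    last = feature_id.split("|")[-1]
    return _RANK_RE.sub("", last)


def phylum_of(feature_id: str) -> str | None:
    return lineage_ranks(feature_id).get("p")


def _is_species_level(feature_id: str) -> bool:
    ranks = lineage_ranks(feature_id)
    return "s" in ranks and "t" not in ranks


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance_table(path: str | Path, layout: str = "taxa_merged") -> AbundanceTable:
    """Read a feature x sample TSV and return a closed samples x features table.

    ``taxa_merged`` keeps only species-level lineage rows (a species rank and
    no strain rank); bare feature ids (no rank prefixes) are kept as-is.
    ``pathway`` drops stratified (taxon-attributed, ``|``-containing) rows,
    keeping community totals.
    """
    if layout not in ("taxa_merged", "pathway"):
        raise TableError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise TableError(f"empty table: {path}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()]
        raise TableError(f"duplicate feature rows in {path}: {list(dups)[:5]}")
    feature_ids = df.index.astype(str)
    if layout == "taxa_merged":
        has_ranks = feature_ids.str.contains(r"[a-z]__", regex=True)
        if has_ranks.any():
            keep = [fid for fid in feature_ids if _is_species_level(fid)]
            df = df.loc[keep]
    else:  # pathway
        keep = [fid for fid in feature_ids if "|" not in fid]
        df = df.loc[keep]
    if df.shape[0] == 0:
        raise TableError(f"no rows left after {layout} filtering: {path}")
    values = df.T.astype(float)  # samples x features
    table = AbundanceTable(values, unit_scale="percent" if _looks_percent(values) else "fraction")
    if not table.is_closed():
        logger.info("table %s not closed; renormalizing rows to unit sum", path)
    return table.close()


def _looks_percent(values: pd.DataFrame) -> bool:
    sums = values.sum(axis=1)
    return bool(np.allclose(sums, 100.0, atol=1.0))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write features x samples TSV (inverse of :func:`read_abundance_table`)."""
    table.values.T.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical TSV.

    Required columns: sample_id (first), patient_id, timepoint.  Unknown
    columns are preserved as extra parameters; blank numeric cells stay
    missing (NaN), never zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    for col in REQUIRED_CLINICAL:
        if col not in df.columns:
            raise TableError(f"clinical table {path} missing column {col!r}")
    df["patient_id"] = df["patient_id"].astype(str)
    for col in df.columns:
        if col in ("patient_id", "timepoint", "cancer_type"):
            continue
        df[col] = pd.to_numeric(df[col], errors="raise")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path: str | Path) -> OxygenAnnotation:
    """Read a two-column feature_id<TAB>class map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "class"],
                     dtype=str, comment="#")
    return OxygenAnnotation(dict(zip(df["feature_id"], df["class"])))


def write_annotation(annotation: OxygenAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in annotation.classes.items():
            fh.write(f"{k}\t{v}\n")


def build_pairs(clinical: ClinicalTable, table: AbundanceTable) -> PairedDesign:
    """Pair each patient's pre/post samples present in the abundance table.

    Patients missing either timepoint in the table are dropped with a logged
    warning; zero complete pairs is an error.
    """
    known = set(clinical.sample_ids)
    orphan = [s for s in table.sample_ids if s not in known]
    if len(orphan) == len(table.sample_ids):
        raise TableError("abundance table shares no samples with the clinical table")
    available = set(table.sample_ids)
    pairs: list[tuple[str, str, str]] = []
    for patient, grp in clinical.data.groupby("patient_id"):
        by_tp = dict(zip(grp["timepoint"], grp.index))
        pre, post = by_tp.get("pre"), by_tp.get("post")
        if pre in available and post in available:
            pairs.append((str(patient), pre, post))
        else:
            logger.warning("patient %s lacks a complete pre/post pair; dropped", patient)
    if not pairs:
        raise TableError("zero complete pre/post pairs")
    pairs.sort(key=lambda t: t[0])
    return PairedDesign(pairs)
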