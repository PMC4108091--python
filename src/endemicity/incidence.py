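"""Species × area incidence matrices and per-area covariate tables.

The unit of analysis is a biogeographic *area* (in the motivating use case a
freshwater ecoregion) and the raw data are strict presence/absence records of
species across areas.  For parsimony analysis of endemicity (PAE) the matrix
is read transposed relative to ordinary phylogenetics: areas play the role of
taxa and each species is one binary character, with a hypothetical area in
which every species is absent serving as the outgroup that polarises presence
as the derived state.

On disk the matrix is stored with species as rows and areas as columns
(matching the structure of typical occurrence compilations); :func:`write_nexus`
performs the PAE transposition when exporting for parsimony software.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OUTGROUP_LABEL",
    "COVARIATE_COLUMNS",
    "IncidenceError",
    "IncidenceMatrix",
    "read_incidence",
    "richness",
    "drop_uninformative",
    "write_nexus",
    "validate_covariates",
    "read_covariates",
    "load_supplement",
]

#: Reserved label for the hypothetical all-absent outgroup area.
OUTGROUP_LABEL = "ROOT_ALL_ABSENT"

#: Required covariate columns, in the order the richness regression reports them
#: (area first, then altitude and the six bioclimatic summaries).
COVARIATE_COLUMNS = (
    "area",
    "altitude",
    "annual_mean_temp",
    "max_temp_warmest_month",
    "min_temp_coldest_month",
    "annual_precip",
    "precip_driest_month",
    "precip_wettest_month",
)


class IncidenceError(ValueError):
    """Invalid incidence or covariate data."""


def _first_duplicate(labels):
    seen = set()
    for lab in labels:
        if lab in seen:
            return lab
        seen.add(lab)
    return None


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary species × area occurrence matrix.

    Parameters
    ----------
    species_ids
        Ordered unique species labels (rows).
    area_ids
        Ordered unique area labels (columns).
    presence
        ``(n_species, n_areas)`` array of 0/1 values.
    """

    species_ids: tuple
    area_ids: tuple
    presence: np.ndarray

    def __post_init__(self):
        species = tuple(str(s) for s in self.species_ids)
        areas = tuple(str(a) for a in self.area_ids)
        dup = _first_duplicate(species)
        if dup is not None:
            raise IncidenceError(f"duplicate species label: {dup!r}")
        dup = _first_duplicate(areas)
        if dup is not None:
            raise IncidenceError(f"duplicate area label: {dup!r}")
        pres = np.asarray(self.presence)
        if pres.ndim != 2 or pres.shape != (len(species), len(areas)):
            raise IncidenceError(
                f"presence shape {pres.shape} does not match "
                f"{len(species)} species x {len(areas)} areas"
            )
        if len(areas) < 2:
            raise IncidenceError("need at least 2 areas")
        if len(species) < 1:
            raise IncidenceError("need at least 1 species")
        if not np.isin(pres, (0, 1)).all():
            bad = np.argwhere(~np.isin(pres, (0, 1)))[0]
            raise IncidenceError(
                f"non-binary cell at species {species[bad[0]]!r}, "
                f"area {areas[bad[1]]!r}: {pres[tuple(bad)]!r}"
            )
        object.__setattr__(self, "species_ids", species)
        object.__setattr__(self, "area_ids", areas)
        object.__setattr__(self, "presence", pres.astype(np.uint8))

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        """Build from a DataFrame indexed by species with area columns."""
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.copy(),
            index=pd.Index(self.species_ids, name="species"),
            columns=list(self.area_ids),
        )

    def richness(self) -> pd.Series:
        """Species count per area (column sums)."""
        counts = self.presence.sum(axis=0).astype(int)
        return pd.Series(counts, index=pd.Index(self.area_ids, name="area_id"),
                         name="richness")

    def range_sizes(self) -> pd.Series:
        """Number of areas each species occupies (row sums)."""
        return pd.Series(self.presence.sum(axis=1).astype(int),
                         index=pd.Index(self.species_ids, name="species"),
                         name="n_areas")


def read_incidence(path, treat_missing_as_absent: bool = False) -> IncidenceMatrix:
    """Read a delimited-text incidence matrix.

    The first column holds species labels and the remaining header fields name
    the areas.  Comma vs. tab delimiting is auto-detected from the header
    line.  Cells must parse as 0 or 1; empty cells are rejected unless
    ``treat_missing_as_absent`` is set, in which case they are scored 0.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise IncidenceError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(lines, delimiter=delim))
    header = rows[0]
    if len(header) < 3:
        raise IncidenceError(f"{path}: need at least 2 area columns")
    area_ids = [h.strip() for h in header[1:]]
    species_ids = []
    cells = []
    for r, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # blank line
        if len(row) != len(header):
            raise IncidenceError(
                f"{path}: line {r} has {len(row)} fields, expected {len(header)}"
            )
        species_ids.append(row[0].strip())
        vals = []
        for c, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                if treat_missing_as_absent:
                    vals.append(0)
                    continue
                raise IncidenceError(
                    f"{path}: missing cell at line {r}, column {c} "
                    f"(species {row[0].strip()!r}, area {area_ids[c - 2]!r})"
                )
            if cell not in ("0", "1"):
                raise IncidenceError(
                    f"{path}: non-binary cell {cell!r} at line {r}, column {c} "
                    f"(species {row[0].strip()!r}, area {area_ids[c - 2]!r})"
                )
            vals.append(int(cell))
        cells.append(vals)
    return IncidenceMatrix(tuple(species_ids), tuple(area_ids), np.array(cells))


def richness(matrix: IncidenceMatrix) -> pd.Series:
    """Per-area species counts (column sums)."""
    return matrix.richness()


def drop_uninformative(matrix: IncidenceMatrix):
    """Remove species that are parsimony-uninformative under PAE rooting.

    With the all-absent outgroup, a species recorded in fewer than two areas
    cannot group areas (it is absent everywhere, or an autapomorphy of a
    single area) and adds at most a constant to every tree's length.  Such
    species are removed; areas are never removed.

    Returns
    -------
    (IncidenceMatrix, tuple of removed species ids)
    """
    keep = matrix.presence.sum(axis=1) >= 2
    removed = tuple(s for s, k in zip(matrix.species_ids, keep) if not k)
    if not removed:
        return matrix, ()
    if not keep.any():
        raise IncidenceError("no species present in >= 2 areas remain")
    kept_ids = tuple(s for s, k in zip(matrix.species_ids, keep) if k)
    return (IncidenceMatrix(kept_ids, matrix.area_ids, matrix.presence[keep]),
            removed)


_NEXUS_SAFE = re.compile(r"^[A-Za-z0-9_.\-]+$")


def _nexus_label(label: str) -> str:
    if _NEXUS_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(matrix: IncidenceMatrix, include_outgroup: bool = True,
                outgroup_label: str = OUTGROUP_LABEL) -> str:
    """Emit a NEXUS DATA block with areas as taxa and species as characters.

    This is the PAE transposition: ``ntax`` is the number of areas (plus one
    when the all-absent outgroup row is included) and ``nchar`` the number of
    species.
    """
    if include_outgroup and outgroup_label in matrix.area_ids:
        raise IncidenceError(
            f"outgroup label {outgroup_label!r} collides with an area label"
        )
    taxa = list(matrix.area_ids)
    rows = [("".join(str(v) for v in matrix.presence[:, j])) for j in range(matrix.n_areas)]
    if include_outgroup:
        taxa.append(outgroup_label)
        rows.append("0" * matrix.n_species)
    width = max(len(_nexus_label(t)) for t in taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(taxa)} NCHAR={matrix.n_species};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=- INTERLEAVE=NO;',
        "    MATRIX",
    ]
    for t, r in zip(taxa, rows):
        lines.append(f"        {_nexus_label(t):<{width}}{r}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-area covariate table and return it indexed by area_id.

    Requires one row per area with the eight predictor columns
    (:data:`COVARIATE_COLUMNS`); checks the physical invariants: area > 0,
    warmest-month maximum >= coldest-month minimum, precipitation >= 0.
    """
    df = df.copy()
    if "area_id" in df.columns:
        df = df.set_index("area_id")
    df.index = df.index.astype(str)
    df.index.name = "area_id"
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise IncidenceError(f"covariate table missing columns: {missing}")
    dup = _first_duplicate(df.index)
    if dup is not None:
        raise IncidenceError(f"duplicate area_id in covariates: {dup!r}")
    df = df[list(COVARIATE_COLUMNS)].astype(float)
    if (df["area"] <= 0).any():
        bad = df.index[df["area"] <= 0].tolist()
        raise IncidenceError(f"non-positive area for: {bad}")
    viol = df["max_temp_warmest_month"] < df["min_temp_coldest_month"]
    if viol.any():
        raise IncidenceError(
            f"max_temp_warmest_month < min_temp_coldest_month for: "
            f"{df.index[viol].tolist()}"
        )
    for col in ("annual_precip", "precip_driest_month", "precip_wettest_month"):
        if (df[col] < 0).any():
            raise IncidenceError(f"negative {col} for: {df.index[df[col] < 0].tolist()}")
    return df


def read_covariates(path) -> pd.DataFrame:
    """Read and validate a per-area covariate CSV/TSV."""
    sep = "\t" if "\t" in Path(path).read_text(encoding="utf-8").splitlines()[0] else ","
    return validate_covariates(pd.read_csv(path, sep=sep))


def load_supplement(directory):
    """Load an occurrence supplement: ``incidence.csv`` + ``covariates.csv``.

    The compiled neotropical diaptomid dataset this package was designed
    around comprises 98 species scored across 72 freshwater ecoregions; when
    a supplement directory with those tables is available this loader parses
    and cross-validates them.  Raises :class:`FileNotFoundError` when the
    directory or either table is absent.
    """
    directory = Path(directory)
    matrix_path = directory / "incidence.csv"
    cov_path = directory / "covariates.csv"
    if not matrix_path.is_file() or not cov_path.is_file():
        raise FileNotFoundError(
            f"supplement tables not found under {directory} "
            "(expected incidence.csv and covariates.csv)"
        )
    matrix = read_incidence(matrix_path)
    covariates = read_covariates(cov_path)
    return matrix, covariates
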