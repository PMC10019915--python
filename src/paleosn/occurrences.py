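"""Fossil occurrence tables: reading, filtering, and temporal binning.

Occurrence records are the atomic unit of the fossil record as archived in
Paleobiology-Database-style flat files: one row per (genus, collection)
observation, dated by a stratigraphic interval [age_min, age_max] in Ma
before present (larger = older).  All downstream diversity estimation works
on per-time-bin multisets of (genus, collection_id) tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The fourteen major marine animal classes used for the "major animals"
#: genus-diversity extract.
MAJOR_MARINE_TAXA = frozenset({
    "Anthozoa", "Bivalvia", "Brachiopoda", "Bryozoa", "Cephalopoda",
    "Chondrichthyes", "Conodonta", "Crinoidea", "Echinoidea", "Gastropoda",
    "Graptolithina", "Linguliformea", "Ostracoda", "Trilobita",
})

#: Region tags understood by :func:`filter_region`.
REGIONS = ("global", "NH", "SH", "tropics")

#: Default PBDB flat-file column map (file column -> canonical field).
DEFAULT_COLUMN_MAP = {
    "genus": "genus",
    "class": "higher_taxon",
    "collection_no": "collection_id",
    "max_ma": "age_max",
    "min_ma": "age_min",
    "paleolat": "paleolat",
}

_MANDATORY = ("genus", "higher_taxon", "collection_id", "age_max", "age_min")


class ConfigurationError(ValueError):
    """Raised when inputs or options are structurally unusable."""


@dataclass
class OccurrenceTable:
    """Validated occurrence records.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``genus, higher_taxon, collection_id, age_max, age_min``
        and optionally ``paleolat`` (degrees, positive north).
    n_dropped : int
        Rows discarded during reading/validation.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_paleolat(self) -> bool:
        return "paleolat" in self.df.columns

    def to_csv(self, path) -> None:
        """Write back in the PBDB flat-file dialect this package reads."""
        inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
        out = self.df.rename(columns=inv)
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class TimeBin:
    label: str
    age_older: float
    age_younger: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_older + self.age_younger)


@dataclass
class TimeBinScheme:
    """Ordered (old -> young), non-overlapping time bins in Ma."""

    bins: list[TimeBin]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ConfigurationError("bin scheme is empty")
        for b in self.bins:
            if not b.age_older > b.age_younger:
                raise ConfigurationError(
                    f"bin {b.label!r}: age_older must exceed age_younger")
            if b.age_younger < 0:
                raise ConfigurationError(f"bin {b.label!r}: negative age")
        for prev, cur in zip(self.bins, self.bins[1:]):
            if cur.age_older > prev.age_younger + 1e-9:
                raise ConfigurationError(
                    f"bins {prev.label!r} and {cur.label!r} overlap or are "
                    "out of old->young order")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bins])

    @classmethod
    def uniform(cls, age_oldest: float = 520.0, width: float = 5.0,
                age_youngest: float = 0.0) -> "TimeBinScheme":
        """Uniform bins covering [age_youngest, age_oldest], old -> young."""
        edges = np.arange(age_oldest, age_youngest - 1e-9, -width)
        bins = []
        for older in edges:
            younger = max(older - width, age_youngest)
            if older - younger <= 1e-9:
                break
            bins.append(TimeBin(f"{older:g}-{younger:g}", float(older),
                                float(younger)))
        return cls(bins)

    @classmethod
    def from_csv(cls, path) -> "TimeBinScheme":
        df = pd.read_csv(path)
        need = {"label", "age_older_Ma", "age_younger_Ma"}
        if not need <= set(df.columns):
            raise ConfigurationError(
                f"bin scheme file must have columns {sorted(need)}")
        return cls([TimeBin(str(r.label), float(r.age_older_Ma),
                            float(r.age_younger_Ma))
                    for r in df.itertuples()])

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "label": [b.label for b in self.bins],
            "age_older_Ma": [b.age_older for b in self.bins],
            "age_younger_Ma": [b.age_younger for b in self.bins],
        }).to_csv(path, index=False)


@dataclass
class BinnedOccurrences:
    """Per-bin (genus, collection_id) tokens, plus bookkeeping.

    ``tokens`` maps each bin label of the scheme to a DataFrame with columns
    ``genus`` and ``collection_id`` (possibly empty).  ``n_unassigned``
    counts records that fit no bin under the chosen rule, so that
    assigned + unassigned equals the input record count.
    """

    scheme: TimeBinScheme
    tokens: dict[str, pd.DataFrame]
    n_unassigned: int
    region: str = "global"

    @property
    def n_assigned(self) -> int:
        return sum(len(t) for t in self.tokens.values())


def read_occurrences(path, column_map: dict[str, str] | None = None
                     ) -> OccurrenceTable:
    """Read a delimited occurrence file into a validated table.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row.
    column_map : dict, optional
        Maps file column names to canonical fields
        (default: PBDB dialect, see :data:`DEFAULT_COLUMN_MAP`).

    Rows failing validation (empty genus, unparseable or inverted ages,
    negative ages) are dropped and counted in ``n_dropped``.
    Missing mandatory columns raise :class:`ConfigurationError`.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    raw = pd.read_csv(path)
    present = {src: dst for src, dst in column_map.items()
               if src in raw.columns}
    df = raw[list(present)].rename(columns=present)
    missing = [m for m in _MANDATORY if m not in df.columns]
    if missing:
        raise ConfigurationError(
            f"occurrence file lacks mandatory column(s) {missing} "
            f"(after applying column map)")

    n_in = len(df)
    df = df.copy()
    for col in ("age_max", "age_min"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "paleolat" in df.columns:
        df["paleolat"] = pd.to_numeric(df["paleolat"], errors="coerce")
    genus = df["genus"].astype("string")
    ok = (
        genus.notna() & (genus.str.strip() != "")
        & df["age_max"].notna() & df["age_min"].notna()
        & (df["age_max"] >= df["age_min"]) & (df["age_min"] >= 0)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("read_occurrences: dropped %d of %d rows failing "
                       "validation", dropped, n_in)
    out = df[ok].reset_index(drop=True)
    out["genus"] = out["genus"].astype(str).str.strip()
    out["higher_taxon"] = out["higher_taxon"].astype(str).str.strip()
    return OccurrenceTable(out, n_dropped=dropped)


def filter_major_taxa(table: OccurrenceTable,
                      taxa: frozenset | set | None = None) -> OccurrenceTable:
    """Keep records whose higher taxon is in ``taxa``.

    Defaults to the fourteen-class major-marine-animal list
    (:data:`MAJOR_MARINE_TAXA`).  An empty result is a warning, not an
    error.
    """
    taxa = set(taxa) if taxa is not None else set(MAJOR_MARINE_TAXA)
    if not taxa:
        raise ConfigurationError("taxa filter set is empty")
    kept = table.df[table.df["higher_taxon"].isin(taxa)].reset_index(drop=True)
    if len(kept) == 0:
        logger.warning("filter_major_taxa: no records match the taxon list")
    return OccurrenceTable(kept, n_dropped=table.n_dropped)


def filter_region(table: OccurrenceTable, region: str) -> OccurrenceTable:
    """Restrict records by paleolatitude band.

    ``NH`` keeps paleolat > 0, ``SH`` paleolat < 0, ``tropics`` the open
    interval (-30, 30); paleolat exactly 0 belongs to neither hemisphere.
    ``global`` is the identity.  Records without a paleolatitude are
    dropped (and logged) for non-global regions.
    """
    if region not in REGIONS:
        raise ConfigurationError(f"unknown region {region!r}; "
                                 f"expected one of {REGIONS}")
    if region == "global":
        return table
    if not table.has_paleolat:
        raise ConfigurationError(
            f"region {region!r} requires a paleolat column")
    lat = table.df["paleolat"]
    n_missing = int(lat.isna().sum())
    if n_missing:
        logger.warning("filter_region(%s): dropping %d records without "
                       "paleolatitude", region, n_missing)
    if region == "NH":
        keep = lat > 0
    elif region == "SH":
        keep = lat < 0
    else:  # tropics, open interval as printed
        keep = (lat > -30) & (lat < 30)
    return OccurrenceTable(table.df[keep.fillna(False)].reset_index(drop=True),
                           n_dropped=table.n_dropped)


def bin_occurrences(table: OccurrenceTable, scheme: TimeBinScheme,
                    rule: str = "contained",
                    region: str = "global") -> BinnedOccurrences:
    """Assign occurrence records to time bins.

    rule="contained"
        A record goes to a bin iff its age interval lies entirely inside
        the bin; stratigraphically unresolvable records are left
        unassigned (counted, logged).
    rule="midpoint"
        A record goes to the bin containing its interval midpoint
        (half-open on the young edge, so bins partition the span).
    """
    if rule not in ("contained", "midpoint"):
        raise ConfigurationError(f"unknown binning rule {rule!r}")
    older = np.array([b.age_older for b in scheme.bins])
    younger = np.array([b.age_younger for b in scheme.bins])
    amax = table.df["age_max"].to_numpy(float)
    amin = table.df["age_min"].to_numpy(float)

    if rule == "contained":
        inside = (amax[:, None] <= older[None, :] + 1e-9) & \
                 (amin[:, None] >= younger[None, :] - 1e-9)
    else:
        mid = 0.5 * (amax + amin)
        inside = (mid[:, None] <= older[None, :]) & \
                 (mid[:, None] > younger[None, :])
        # the youngest bin is closed at its young edge so age 0 is binnable
        inside[:, -1] |= (mid <= older[-1]) & (mid >= younger[-1])
    hit = inside.any(axis=1)
    idx = inside.argmax(axis=1)

    tokens: dict[str, pd.DataFrame] = {}
    cols = ["genus", "collection_id"]
    for i, b in enumerate(scheme.bins):
        sel = hit & (idx == i)
        tokens[b.label] = table.df.loc[sel, cols].reset_index(drop=True)
    n_un = int((~hit).sum())
    if n_un:
        logger.info("bin_occurrences(%s): %d of %d records unassigned",
                    rule, n_un, len(table))
    return BinnedOccurrences(scheme, tokens, n_un, region=region)
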