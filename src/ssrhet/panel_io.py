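"""Data model and tabular I/O for mixed-ploidy SSR genotype panels.

The central object is the :class:`GenotypePanel`: a matrix of individuals
(diploid cultivars and their autotetraploid derivatives) by microsatellite
loci, where each cell is the *set* of allele labels scored for that
individual.  Because band scoring on gels cannot resolve allele dosage in a
tetraploid, a call stores between 1 and ``ploidy`` distinct labels and defers
any dosage interpretation to downstream frequency modes.

Allele labels are opaque strings: a label like ``"153"`` (a band size) is
legal but never interpreted numerically.  A missing call is represented by
``None`` (the module-level :data:`MISSING` sentinel).

Serialization is plain delimited text (tab or comma, auto-detected):

* genotype table — metadata columns ``id, ploidy, subgroup, pair_id``
  followed by one column per marker, header ``name:chromosome`` (a bare
  ``name`` defaults to chromosome 1); cells are allele labels joined by
  ``/`` with ``.`` for missing;
* trait table — long format ``entity, trait, replicate, value`` with an
  optional ``trait, direction`` sidecar;
* cross plan — ``female, male, hybrid_id, ploidy, counterpart_2x_hybrid``.
"""
from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING = None

DEFAULT_ALLELE_SEP = "/"
DEFAULT_MISSING_TOKEN = "."

_META_COLUMNS = ("id", "ploidy", "subgroup", "pair_id")


class PanelFormatError(ValueError):
    """Raised when a serialized table or an in-memory panel violates the data model."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDef:
    """An SSR marker: a name unique within the panel and its chromosome."""

    name: str
    chromosome: int = 1

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelFormatError("marker name must be non-empty")
        if self.chromosome < 1:
            raise PanelFormatError(
                f"marker {self.name!r}: chromosome must be >= 1, got {self.chromosome}"
            )


@dataclass(frozen=True)
class IndividualMeta:
    """One cultivar/line: id, ploidy (2 or 4), optional subgroup and pair link.

    ``pair_id`` ties a diploid cultivar to its colchicine-derived
    autotetraploid line; at most one individual of each ploidy may share it.
    """

    id: str
    ploidy: int
    subgroup: str | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelFormatError("individual id must be non-empty")
        if self.ploidy not in (2, 4):
            raise PanelFormatError(
                f"individual {self.id!r}: ploidy must be 2 or 4, got {self.ploidy}"
            )


GenotypeCall = frozenset  # frozenset[str] | None(MISSING)


def make_call(alleles: Iterable[str]) -> frozenset:
    """Build a genotype call from allele labels (validated against ploidy later)."""
    call = frozenset(str(a) for a in alleles)
    if not call:
        raise PanelFormatError("a genotype call needs at least one allele label")
    return call


@dataclass
class GenotypePanel:
    """Individuals x markers matrix of allele-set calls with ploidy metadata."""

    markers: list[MarkerDef]
    individuals: list[IndividualMeta]
    calls: list[list[frozenset | None]]  # [individual][marker]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelFormatError(f"duplicate marker names: {dup}")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelFormatError(f"duplicate individual ids: {dup}")
        if len(self.calls) != len(self.individuals):
            raise PanelFormatError(
                f"call matrix has {len(self.calls)} rows for {len(self.individuals)} individuals"
            )
        for ind, row in zip(self.individuals, self.calls):
            if len(row) != len(self.markers):
                raise PanelFormatError(
                    f"individual {ind.id!r}: {len(row)} calls for {len(self.markers)} markers"
                )
            for marker, call in zip(self.markers, row):
                if call is MISSING:
                    continue
                if not isinstance(call, frozenset) or not call:
                    raise PanelFormatError(
                        f"cell ({ind.id!r}, {marker.name!r}): calls must be non-empty "
                        f"frozensets or MISSING"
                    )
                if len(call) > ind.ploidy:
                    raise PanelFormatError(
                        f"cell ({ind.id!r}, {marker.name!r}): {len(call)} alleles exceed "
                        f"ploidy {ind.ploidy}"
                    )
        # pair_id: at most one individual of each ploidy
        seen: dict[tuple[str, int], str] = {}
        for ind in self.individuals:
            if ind.pair_id is None:
                continue
            key = (ind.pair_id, ind.ploidy)
            if key in seen:
                raise PanelFormatError(
                    f"pair_id {ind.pair_id!r} used by two {ind.ploidy}x individuals "
                    f"({seen[key]!r}, {ind.id!r})"
                )
            seen[key] = ind.id

    # -- accessors ---------------------------------------------------------
    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def individual_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def marker_index(self, locus: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == locus:
                return i
        raise KeyError(f"unknown locus {locus!r}")

    def individual_index(self, individual_id: str) -> int:
        for i, ind in enumerate(self.individuals):
            if ind.id == individual_id:
                return i
        raise KeyError(f"unknown individual {individual_id!r}")

    def column(self, locus: str) -> list[frozenset | None]:
        j = self.marker_index(locus)
        return [row[j] for row in self.calls]

    def alleles_at(self, locus: str) -> list[str]:
        """Distinct allele labels observed at a locus, sorted."""
        labels: set[str] = set()
        for call in self.column(locus):
            if call is not MISSING:
                labels |= call
        return sorted(labels)

    def subset(self, individual_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.individual_index(i) for i in individual_ids]
        return GenotypePanel(
            markers=list(self.markers),
            individuals=[self.individuals[i] for i in idx],
            calls=[list(self.calls[i]) for i in idx],
        )

    def pair_map(self) -> dict[str, tuple[str, str]]:
        """pair_id -> (diploid id, tetraploid id) for complete pairs."""
        by_pair: dict[str, dict[int, str]] = {}
        for ind in self.individuals:
            if ind.pair_id is not None:
                by_pair.setdefault(ind.pair_id, {})[ind.ploidy] = ind.id
        return {
            pid: (members[2], members[4])
            for pid, members in sorted(by_pair.items())
            if 2 in members and 4 in members
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.individuals == other.individuals
            and self.calls == other.calls
        )


@dataclass
class TraitTable:
    """Replicate-level phenotypes in long format with per-trait direction flags.

    ``direction[trait]`` is True when larger values are agronomically better
    (the default for every trait); heterosis statistics use it to pick the
    better parent.
    """

    data: pd.DataFrame  # columns: entity, trait, replicate, value
    directions: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["entity", "trait", "replicate", "value"]
        if list(self.data.columns[:4]) != required:
            raise PanelFormatError(f"trait table needs columns {required}")
        dup = self.data.duplicated(subset=["entity", "trait", "replicate"])
        if dup.any():
            bad = self.data.loc[dup, ["entity", "trait", "replicate"]].iloc[0].tolist()
            raise PanelFormatError(f"duplicated (entity, trait, replicate) key: {bad}")
        if not pd.api.types.is_numeric_dtype(self.data["value"]):
            raise PanelFormatError("trait values must be numeric")
        for t in self.traits:
            self.directions.setdefault(t, True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def entities(self) -> list[str]:
        return sorted(self.data["entity"].unique())

    def replicates(self, entity: str, trait: str) -> pd.Series:
        mask = (self.data["entity"] == entity) & (self.data["trait"] == trait)
        return self.data.loc[mask, "value"]

    def entity_mean(self, entity: str, trait: str) -> float:
        vals = self.replicates(entity, trait)
        if vals.empty:
            return math.nan
        return float(vals.mean())

    def means_wide(self) -> pd.DataFrame:
        """Entity x trait matrix of replicate means."""
        return self.data.pivot_table(
            index="entity", columns="trait", values="value", aggfunc="mean"
        )


@dataclass(frozen=True)
class Cross:
    female: str
    male: str
    hybrid_id: str
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise PanelFormatError(
                f"cross {self.hybrid_id!r}: ploidy must be 2 or 4, got {self.ploidy}"
            )


@dataclass
class CrossPlan:
    """Diallel cross list plus the 4x-hybrid -> counterpart-2x-hybrid map."""

    crosses: list[Cross]
    counterpart: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.hybrid_id for c in self.crosses]
        if len(set(ids)) != len(ids):
            raise PanelFormatError("duplicate hybrid ids in cross plan")
        by_id = {c.hybrid_id: c for c in self.crosses}
        if len(set(self.counterpart.values())) != len(self.counterpart):
            raise PanelFormatError("counterpart map is not injective")
        for h4, h2 in self.counterpart.items():
            if h4 not in by_id or h2 not in by_id:
                raise PanelFormatError(
                    f"counterpart pair ({h4!r}, {h2!r}) references unknown hybrids"
                )
            c4, c2 = by_id[h4], by_id[h2]
            if c4.ploidy != 4 or c2.ploidy != 2:
                raise PanelFormatError(
                    f"counterpart pair ({h4!r}, {h2!r}) must map a 4x hybrid to a 2x hybrid"
                )
            if (strip_ploidy_suffix(c4.female) != strip_ploidy_suffix(c2.female)
                    or strip_ploidy_suffix(c4.male) != strip_ploidy_suffix(c2.male)):
                raise PanelFormatError(
                    f"counterpart pair ({h4!r}, {h2!r}) crosses different cultivars"
                )

    def by_ploidy(self, ploidy: int) -> list[Cross]:
        return [c for c in self.crosses if c.ploidy == ploidy]

    def cross(self, hybrid_id: str) -> Cross:
        for c in self.crosses:
            if c.hybrid_id == hybrid_id:
                return c
        raise KeyError(f"unknown hybrid {hybrid_id!r}")


_SUFFIX_RE = re.compile(r"[-_ ]?[24][xX]$")


def strip_ploidy_suffix(name: str) -> str:
    """Drop a trailing '-2x'/'-4x' style ploidy tag from a cultivar name."""
    return _SUFFIX_RE.sub("", name)


def infer_pairs_from_names(individuals: Sequence[IndividualMeta]) -> list[IndividualMeta]:
    """Fill pair_id from '-2x'/'-4x' name suffixes where it is unambiguous.

    Helper for panels whose pairing was encoded only in cultivar names; the
    explicit pair_id metadata remains authoritative and is never overwritten.
    """
    base_members: dict[str, list[IndividualMeta]] = {}
    for ind in individuals:
        base_members.setdefault(strip_ploidy_suffix(ind.id), []).append(ind)
    out = []
    for ind in individuals:
        base = strip_ploidy_suffix(ind.id)
        members = base_members[base]
        ploidies = sorted(m.ploidy for m in members)
        if ind.pair_id is None and base != ind.id and ploidies == [2, 4]:
            out.append(replace(ind, pair_id=base))
        else:
            out.append(ind)
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    sample = Path(path).read_text().splitlines()[0]
    return "\t" if "\t" in sample else ","


def _parse_marker_header(token: str) -> MarkerDef:
    if ":" in token:
        name, _, chrom = token.rpartition(":")
        try:
            return MarkerDef(name=name, chromosome=int(chrom))
        except ValueError as exc:
            raise PanelFormatError(f"bad marker header {token!r}") from exc
    return MarkerDef(name=token, chromosome=1)


def read_genotype_table(
    path: str | Path,
    allele_sep: str = DEFAULT_ALLELE_SEP,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> GenotypePanel:
    """Read a delimited genotype table into a validated :class:`GenotypePanel`.

    Malformed cells (more labels than the row's ploidy) are rejected with the
    offending individual and marker named.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header is None:
            raise PanelFormatError(f"{path}: empty file")
        header = [h.strip() for h in header]
        if tuple(h.lower() for h in header[:4]) != _META_COLUMNS:
            raise PanelFormatError(
                f"{path}: first four columns must be {_META_COLUMNS}, got {header[:4]}"
            )
        markers = [_parse_marker_header(tok) for tok in header[4:]]
        individuals: list[IndividualMeta] = []
        calls: list[list[frozenset | None]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4 + len(markers):
                raise PanelFormatError(
                    f"{path}:{lineno}: expected {4 + len(markers)} columns, got {len(row)}"
                )
            ind_id, ploidy_s, subgroup, pair_id = (c.strip() for c in row[:4])
            try:
                ploidy = int(ploidy_s)
            except ValueError:
                raise PanelFormatError(
                    f"{path}:{lineno}: unknown ploidy value {ploidy_s!r}"
                ) from None
            meta = IndividualMeta(
                id=ind_id,
                ploidy=ploidy,
                subgroup=subgroup or None,
                pair_id=pair_id or None,
            )
            row_calls: list[frozenset | None] = []
            for marker, cell in zip(markers, row[4:]):
                cell = cell.strip()
                if cell == missing_token or cell == "":
                    row_calls.append(MISSING)
                    continue
                labels = [tok for tok in cell.split(allele_sep) if tok]
                if not labels:
                    raise PanelFormatError(
                        f"{path}:{lineno}: empty call in column {marker.name!r}"
                    )
                call = frozenset(labels)
                if len(call) > meta.ploidy:
                    raise PanelFormatError(
                        f"{path}:{lineno}: cell ({ind_id!r}, {marker.name!r}) has "
                        f"{len(call)} alleles but ploidy is {meta.ploidy}"
                    )
                row_calls.append(call)
            individuals.append(meta)
            calls.append(row_calls)
    return GenotypePanel(markers=markers, individuals=individuals, calls=calls)


def write_genotype_table(
    panel: GenotypePanel,
    path: str | Path,
    allele_sep: str = DEFAULT_ALLELE_SEP,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    delimiter: str = "\t",
) -> None:
    """Serialize a panel; ``read_genotype_table`` round-trips it field-for-field."""
    if not panel.markers:
        raise PanelFormatError("cannot serialize a panel with no markers")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(
            list(_META_COLUMNS) + [f"{m.name}:{m.chromosome}" for m in panel.markers]
        )
        for ind, row in zip(panel.individuals, panel.calls):
            cells = []
            for call in row:
                if call is MISSING:
                    cells.append(missing_token)
                else:
                    cells.append(allele_sep.join(sorted(call)))
            writer.writerow(
                [ind.id, ind.ploidy, ind.subgroup or "", ind.pair_id or ""] + cells
            )


def read_trait_table(
    path: str | Path, direction_sidecar: str | Path | None = None
) -> TraitTable:
    """Read a long-format trait table; 'NA'/empty replicate values are dropped
    with a logged warning, any other non-numeric value is rejected."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    needed = ["entity", "trait", "replicate", "value"]
    if [c.strip().lower() for c in df.columns[:4]] != needed:
        raise PanelFormatError(f"{path}: expected columns {needed}, got {list(df.columns)}")
    df.columns = [c.strip().lower() for c in df.columns]
    na_mask = df["value"].isna() | df["value"].str.strip().isin({"", "NA", "NaN", "nan"})
    if na_mask.any():
        logger.warning(
            "%s: dropping %d replicate(s) with missing values", path, int(na_mask.sum())
        )
        df = df.loc[~na_mask]
    try:
        values = df["value"].astype(float)
    except ValueError as exc:
        raise PanelFormatError(f"{path}: non-numeric trait value ({exc})") from None
    out = df[["entity", "trait", "replicate"]].copy()
    out["value"] = values
    out = out.reset_index(drop=True)

    directions: dict[str, bool] = {}
    if direction_sidecar is not None:
        side = pd.read_csv(direction_sidecar, sep=None, engine="python")
        for _, r in side.iterrows():
            directions[str(r.iloc[0])] = _parse_direction(r.iloc[1])
    return TraitTable(data=out, directions=directions)


def _parse_direction(token: object) -> bool:
    s = str(token).strip().lower()
    if s in {"1", "true", "larger", "larger-is-better", "+", "up"}:
        return True
    if s in {"0", "-1", "false", "smaller", "smaller-is-better", "-", "down"}:
        return False
    raise PanelFormatError(f"unknown direction flag {token!r}")


def write_trait_table(
    table: TraitTable, path: str | Path, direction_sidecar: str | Path | None = None
) -> None:
    table.data.to_csv(path, sep="\t", index=False)
    if direction_sidecar is not None:
        pd.DataFrame(
            {
                "trait": list(table.directions),
                "direction": [
                    "larger-is-better" if v else "smaller-is-better"
                    for v in table.directions.values()
                ],
            }
        ).to_csv(direction_sidecar, sep="\t", index=False)


def read_crossplan(path: str | Path) -> CrossPlan:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    needed = ["female", "male", "hybrid_id", "ploidy", "counterpart_2x_hybrid"]
    if [c.strip().lower() for c in df.columns] != needed:
        raise PanelFormatError(f"{path}: expected columns {needed}")
    crosses = []
    counterpart = {}
    for _, r in df.iterrows():
        cross = Cross(
            female=r["female"], male=r["male"], hybrid_id=r["hybrid_id"],
            ploidy=int(r["ploidy"]),
        )
        crosses.append(cross)
        cp = r["counterpart_2x_hybrid"]
        if isinstance(cp, str) and cp.strip():
            counterpart[cross.hybrid_id] = cp.strip()
    return CrossPlan(crosses=crosses, counterpart=counterpart)


def write_crossplan(plan: CrossPlan, path: str | Path) -> None:
    rows = []
    for c in plan.crosses:
        rows.append(
            {
                "female": c.female,
                "male": c.male,
                "hybrid_id": c.hybrid_id,
                "ploidy": c.ploidy,
                "counterpart_2x_hybrid": plan.counterpart.get(c.hybrid_id, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel manipulation
# ---------------------------------------------------------------------------

def split_by_ploidy(panel: GenotypePanel) -> tuple[GenotypePanel, GenotypePanel]:
    """Partition a panel into its diploid and tetraploid sub-panels.

    Markers are unchanged; the two sub-panels partition the individuals, so
    their sizes always sum to the input size.
    """
    idx2 = [ind.id for ind in panel.individuals if ind.ploidy == 2]
    idx4 = [ind.id for ind in panel.individuals if ind.ploidy == 4]
    return panel.subset(idx2), panel.subset(idx4)


def empty_panel(markers: Iterable[MarkerDef] = ()) -> GenotypePanel:
    return GenotypePanel(markers=list(markers), individuals=[], calls=[])
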