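"""Mapping cross-links onto structures and scoring restraint satisfaction.

Each cross-link, combined with the linker's distance-bound calculus
(:mod:`xlms.linkerchem`), becomes a one-sided Calpha-Calpha restraint.
Satisfaction is scored with a flat-harmonic penalty: zero inside the
allowed distance, quadratic growth ``((d - tol)/sd)**2`` outside.  The
module also writes Rosetta-dialect ``AtomPair ... FLAT_HARMONIC``
constraint files, collapses redundant observations into non-redundant
residue-pair constraints, and selects models ranked well by both total
energy and constraint score.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import pandas as pd

from xlms import linkerchem, structio
from xlms.linkerchem import LinkerSpec
from xlms.structio import ResidueRef, SequenceMap, StructureModel


class EmptyScoreError(ValueError):
    """No mappable cross-link was available to score."""


@dataclass
class CrossLink:
    """One observed residue-residue cross-link.

    Sites are stored in canonical order (sorted by protein id, then
    position) so the unordered pair identifies a non-redundant constraint.
    ``alternatives`` lists additional site pairs for ambiguous photo links;
    assessment scores the minimum-distance alternative.
    """

    id: str
    site_a: ResidueRef
    site_b: ResidueRef
    linker_name: str
    evidence_count: int = 1
    alternatives: tuple = ()

    def __post_init__(self):
        if self.evidence_count < 1:
            raise ValueError("evidence_count must be >= 1")
        if self.site_b.key < self.site_a.key:
            self.site_a, self.site_b = self.site_b, self.site_a

    @property
    def intra_or_inter(self) -> str:
        return "intra" if self.site_a.protein_id == self.site_b.protein_id else "inter"

    @property
    def pair_key(self) -> tuple:
        return (self.site_a.key, self.site_b.key)

    def site_pairs(self) -> list[tuple[ResidueRef, ResidueRef]]:
        return [(self.site_a, self.site_b), *self.alternatives]


@dataclass(frozen=True)
class FlatHarmonicParams:
    """Flat-harmonic restraint: zero penalty within ``tol`` of ``x0``,
    then ``weight * ((|d - x0| - tol)/sd)**2``.

    With ``x0 = 0`` and non-negative distances this is a pure upper-bound
    restraint at ``tol``.
    """

    tol: float
    x0: float = 0.0
    sd: float = 1.0
    weight: float = 1.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class DistanceAssessment:
    """A cross-link evaluated on one structural model."""

    crosslink_id: str
    model_id: str
    distance: float | None
    bound_none: float
    bound_base: float
    bound_md: float
    status: str  # within | tolerated | violated | unmappable
    penalty: float


@dataclass(frozen=True)
class ScoreRow:
    model_id: str
    total_score: float
    constraint_score: float

    def __post_init__(self):
        if not (math.isfinite(self.total_score) and math.isfinite(self.constraint_score)):
            raise ValueError("scores must be finite")


def flat_harmonic(distance: float, p: FlatHarmonicParams) -> float:
    """Flat-harmonic penalty of a distance under parameters ``p``."""
    excess = abs(distance - p.x0) - p.tol
    if excess <= 0:
        return 0.0
    return p.weight * (excess / p.sd) ** 2


def _resolve_site(
    site: ResidueRef, maps: dict[str, SequenceMap]
) -> tuple[str, int, str] | None:
    smap = maps.get(site.protein_id)
    if smap is None:
        return None
    try:
        resnum, icode = smap.to_structure(site.position)
    except structio.MappingError:
        return None
    return (smap.chain_id, resnum, icode)


def assess(
    xl: CrossLink,
    model: StructureModel,
    maps: dict[str, SequenceMap],
    linkers: dict[str, LinkerSpec] | None = None,
    side_chains: dict[str, float] | None = None,
    sd: float = 1.0,
    penalty_bound_mode: str = "base",
) -> DistanceAssessment:
    """Evaluate one cross-link on one model.

    Unresolvable sites yield ``status='unmappable'`` rather than raising.
    For ambiguous links the minimum distance over the listed site
    alternatives is scored.  Status uses the bound ladder: ``within``
    (<= geometric bound), ``tolerated`` (<= MD bound), ``violated``
    (beyond the MD bound).  The penalty is a flat harmonic with ``tol``
    set by ``penalty_bound_mode`` (default: the base-tolerance bound).
    """
    linker = linkerchem.get_linker(xl.linker_name, linkers)
    bounds = {}
    try:
        for mode in ("none", "base", "md"):
            bounds[mode] = linkerchem.max_ca_distance(
                linker, xl.site_a.aa, xl.site_b.aa, mode, side_chains
            )
    except (linkerchem.ChemistryError, linkerchem.RegistryError):
        bounds = {"none": float("nan"), "base": float("nan"), "md": float("nan")}
        return DistanceAssessment(
            xl.id, model.model_id, None, bounds["none"], bounds["base"], bounds["md"],
            "unmappable", 0.0,
        )

    best: float | None = None
    for ref_a, ref_b in xl.site_pairs():
        loc_a = _resolve_site(ref_a, maps)
        loc_b = _resolve_site(ref_b, maps)
        if loc_a is None or loc_b is None:
            continue
        try:
            d = structio.ca_distance(model, loc_a, loc_b)
        except (structio.MissingResidueError, structio.MissingCalphaError):
            continue
        if best is None or d < best:
            best = d

    if best is None:
        return DistanceAssessment(
            xl.id, model.model_id, None, bounds["none"], bounds["base"], bounds["md"],
            "unmappable", 0.0,
        )
    if best <= bounds["none"]:
        status = "within"
    elif best <= bounds["md"]:
        status = "tolerated"
    else:
        status = "violated"
    params = FlatHarmonicParams(tol=bounds[penalty_bound_mode], sd=sd)
    return DistanceAssessment(
        xl.id, model.model_id, best, bounds["none"], bounds["base"], bounds["md"],
        status, flat_harmonic(best, params),
    )


def constraint_score(
    model: StructureModel,
    xls: list[CrossLink],
    maps: dict[str, SequenceMap],
    linkers: dict[str, LinkerSpec] | None = None,
    side_chains: dict[str, float] | None = None,
    sd: float = 1.0,
    penalty_bound_mode: str = "base",
) -> tuple[float, pd.DataFrame]:
    """Total flat-harmonic penalty over mappable links, plus per-link table.

    Unmappable links are listed in the table but excluded from the sum.
    Raises :class:`EmptyScoreError` when no link is mappable.
    """
    rows = []
    total = 0.0
    n_mappable = 0
    for xl in xls:
        a = assess(xl, model, maps, linkers, side_chains, sd, penalty_bound_mode)
        rows.append(a.__dict__.copy())
        if a.status != "unmappable":
            total += a.penalty
            n_mappable += 1
    if n_mappable == 0:
        raise EmptyScoreError(f"no mappable cross-link on model {model.model_id}")
    return total, pd.DataFrame(rows)


def write_constraints(
    xls: list[CrossLink],
    maps: dict[str, SequenceMap],
    linkers: dict[str, LinkerSpec] | None = None,
    side_chains: dict[str, float] | None = None,
    bound_mode: str = "base",
    sd: float = 1.0,
    overrides: dict[str, FlatHarmonicParams] | None = None,
) -> tuple[str, int]:
    """Emit Rosetta-dialect restraint lines, one per mappable link.

    Line format::

        AtomPair CA <res_i> <chain_i> CA <res_j> <chain_j> FLAT_HARMONIC <x0> <sd> <tol>

    ``tol`` defaults to the link's ``bound_mode`` distance bound;
    ``overrides`` replaces the full parameter set per link id.  Returns
    the file text and the number of skipped (unmappable) links; ordering
    is deterministic (canonical site order, then link id).
    """
    overrides = overrides or {}
    lines = []
    skipped = 0
    for xl in sorted(xls, key=lambda x: (x.pair_key, x.id)):
        loc_a = _resolve_site(xl.site_a, maps)
        loc_b = _resolve_site(xl.site_b, maps)
        if loc_a is None or loc_b is None:
            skipped += 1
            continue
        if xl.id in overrides:
            p = overrides[xl.id]
        else:
            try:
                tol = linkerchem.max_ca_distance(
                    linkerchem.get_linker(xl.linker_name, linkers),
                    xl.site_a.aa, xl.site_b.aa, bound_mode, side_chains,
                )
            except (linkerchem.ChemistryError, linkerchem.RegistryError):
                skipped += 1
                continue
            p = FlatHarmonicParams(tol=tol, sd=sd)
        lines.append(
            f"AtomPair CA {loc_a[1]} {loc_a[0]} CA {loc_b[1]} {loc_b[0]} "
            f"FLAT_HARMONIC {p.x0:.1f} {p.sd:.1f} {p.tol:.1f}"
        )
    return "".join(line + "\n" for line in lines), skipped


def parse_constraints(text: str) -> list[dict]:
    """Re-parse restraint lines written by :func:`write_constraints`."""
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        f = line.split()
        if f[0] != "AtomPair" or f[7] != "FLAT_HARMONIC":
            raise ValueError(f"unrecognized constraint line: {line!r}")
        out.append(
            {
                "atom_i": f[1], "res_i": int(f[2]), "chain_i": f[3],
                "atom_j": f[4], "res_j": int(f[5]), "chain_j": f[6],
                "params": FlatHarmonicParams(
                    x0=float(f[8]), sd=float(f[9]), tol=float(f[10])
                ),
            }
        )
    return out


def nonredundant(xls: list[CrossLink]) -> list[CrossLink]:
    """Collapse observations to one link per unordered residue pair and
    linker class, accumulating evidence counts.  Output order is canonical
    (sorted by site pair, then class)."""
    groups: dict[tuple, CrossLink] = {}
    for xl in xls:
        cls = linkerchem.LINKER_CLASSES.get(xl.linker_name, xl.linker_name)
        key = (xl.pair_key, cls)
        if key in groups:
            groups[key].evidence_count += xl.evidence_count
        else:
            groups[key] = CrossLink(
                id=xl.id,
                site_a=xl.site_a,
                site_b=xl.site_b,
                linker_name=xl.linker_name,
                evidence_count=xl.evidence_count,
                alternatives=xl.alternatives,
            )
    return [groups[k] for k in sorted(groups)]


def select_models(scores: list[ScoreRow], n: int) -> list[str]:
    """Models ranking among the best ``n`` by *both* total score and
    constraint score (lower is better; ties broken by model id).  The
    intersection may be empty."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not scores:
        raise ValueError("score list is empty")
    by_total = sorted(scores, key=lambda r: (r.total_score, r.model_id))[:n]
    by_cst = sorted(scores, key=lambda r: (r.constraint_score, r.model_id))[:n]
    chosen = {r.model_id for r in by_total} & {r.model_id for r in by_cst}
    return sorted(chosen)


# ---------------------------------------------------------------------------
# cross-link table I/O (CSV/TSV dialect)

_XL_COLUMNS = (
    "id", "protein_a", "pos_a", "aa_a", "protein_b", "pos_b", "aa_b",
    "linker", "evidence_count",
)


def read_crosslinks(path, delimiter: str | None = None) -> list[CrossLink]:
    """Read a cross-link table (columns: id, protein_a, pos_a, aa_a,
    protein_b, pos_b, aa_b, linker, evidence_count)."""
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        out = []
        for row in reader:
            out.append(
                CrossLink(
                    id=row["id"],
                    site_a=ResidueRef(row["protein_a"], int(row["pos_a"]), row["aa_a"]),
                    site_b=ResidueRef(row["protein_b"], int(row["pos_b"]), row["aa_b"]),
                    linker_name=row["linker"],
                    evidence_count=int(row.get("evidence_count") or 1),
                )
            )
    return out


def write_crosslinks(xls: list[CrossLink], path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(_XL_COLUMNS)
        for xl in xls:
            w.writerow(
                [
                    xl.id,
                    xl.site_a.protein_id, xl.site_a.position, xl.site_a.aa,
                    xl.site_b.protein_id, xl.site_b.position, xl.site_b.aa,
                    xl.linker_name, xl.evidence_count,
                ]
            )


def assessment_report(assessments: list[DistanceAssessment]) -> pd.DataFrame:
    """Tabular report of assessments (one row per link and model)."""
    return pd.DataFrame([a.__dict__.copy() for a in assessments])
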