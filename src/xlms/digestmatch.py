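"""Precursor-level cross-link identification.

In-silico digestion with one or several proteases, enumeration of
cross-linked peptide-pair candidates respecting linker chemistry, and
matching of observed precursor masses within a ppm tolerance (default
3 ppm, boundary inclusive).  Fixed Cys carbamidomethylation and variable
Met oxidation are the supported modifications.  Photo-amino acids are
carried with the one-letter codes ``z`` (photo-Leu) and ``o`` (photo-Met)
and behave like Leu/Met for cleavage purposes.

MS/MS-level (fragment-intensity) scoring is out of scope; a no-op
signal-to-noise filter hook marks where spectrum-level filtering would
plug in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

from xlms import linkerchem
from xlms.linkerchem import LinkerSpec, N_TERMINUS

PROTON = 1.00727646688
WATER = _pmass.calculate_mass(formula="H2O")

# monoisotopic residue masses; photo-amino acids get their diazirine
# compositions (photo-Leu C5H7N3O, photo-Met C6H9N3O)
RESIDUE_MASSES: dict[str, float] = dict(_pmass.std_aa_mass)
RESIDUE_MASSES["z"] = _pmass.calculate_mass(formula="C5H7N3O")
RESIDUE_MASSES["o"] = _pmass.calculate_mass(formula="C6H9N3O")

CARBAMIDOMETHYL = _pmass.calculate_mass(formula="C2H3NO")  # +57.02146 on Cys
OXIDATION = _pmass.calculate_mass(formula="O")  # +15.99491 on Met


class DigestError(ValueError):
    pass


class MassError(KeyError):
    """Residue or modification without a registered mass."""


@dataclass(frozen=True)
class EnzymeRule:
    """C-terminal cleavage rule of one protease."""

    name: str
    cleavage_residues: frozenset
    max_missed: int = 2

    def __post_init__(self):
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")


TRYPSIN = EnzymeRule("trypsin", frozenset("KR"))
CHYMOTRYPSIN = EnzymeRule("chymotrypsin", frozenset("YWF"))
GLUC = EnzymeRule("gluc", frozenset("E"))

ENZYMES = {e.name: e for e in (TRYPSIN, CHYMOTRYPSIN, GLUC)}


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide in construct numbering (1-based, inclusive).

    ``var_mods`` holds (construct position, name) pairs; only Met
    oxidation (``'ox'``) is recognized.  Cys carbamidomethylation is
    applied implicitly as a fixed modification.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    var_mods: tuple = ()

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match start/end span")
        for pos, name in self.var_mods:
            if not (self.start <= pos <= self.end):
                raise ValueError(f"modification at {pos} outside peptide span")
            if name == "ox" and self.sequence[pos - self.start] not in ("M", "o"):
                raise ValueError("oxidation is only allowed on Met")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class XLCandidate:
    """A cross-linked peptide pair with explicit link sites."""

    alpha: Peptide
    beta: Peptide
    link_pos_alpha: int  # construct position of the linked residue
    link_pos_beta: int
    linker_name: str

    def __post_init__(self):
        if not self.alpha.contains(self.link_pos_alpha):
            raise ValueError("alpha link site outside alpha peptide")
        if not self.beta.contains(self.link_pos_beta):
            raise ValueError("beta link site outside beta peptide")


# ---------------------------------------------------------------------------
# digestion


def _photo_free(sequence: str) -> str:
    """Photo codes behave like their parent residues for cleavage."""
    return sequence.replace("z", "L").replace("o", "M")


def digest(
    sequence: str,
    rules: list[EnzymeRule],
    protein_id: str = "protein",
    missed_budget: str = "shared",
    shared_max_missed: int = 2,
    no_cleave_before_pro: bool = True,
) -> list[Peptide]:
    """Exhaustive in-silico digest under one or several protease rules.

    Cleavage happens C-terminal to the union of all cleavage residues
    (standard exception: not before Pro, toggleable).  The missed-cleavage
    allowance is either a ``shared`` budget over all enzymes
    (``shared_max_missed`` internal sites per peptide, default 2) or
    ``per_enzyme`` (each rule's ``max_missed`` applies to its own internal
    sites).  Returns duplicate-free peptides with construct coordinates.
    """
    if not sequence:
        raise DigestError("empty sequence")
    if not rules:
        raise DigestError("no enzyme rules given")
    plain = _photo_free(sequence)
    n = len(sequence)
    # cut after index i (0-based); record which enzyme owns the site
    sites: list[tuple[int, frozenset]] = []
    for i in range(n - 1):
        owners = frozenset(r.name for r in rules if plain[i] in r.cleavage_residues)
        if owners and not (no_cleave_before_pro and plain[i + 1] == "P"):
            sites.append((i, owners))
    boundaries = [0] + [i + 1 for i, _ in sites] + [n]
    site_at = {i + 1: owners for i, owners in sites}
    budgets = {r.name: r.max_missed for r in rules}
    peptides: list[Peptide] = []
    for si in range(len(boundaries) - 1):
        for sj in range(si + 1, len(boundaries)):
            start, end = boundaries[si], boundaries[sj]
            internal = [b for b in boundaries[si + 1 : sj]]
            if missed_budget == "shared":
                if len(internal) > shared_max_missed:
                    break
            elif missed_budget == "per_enzyme":
                per = {r.name: 0 for r in rules}
                for b in internal:
                    for owner in site_at[b]:
                        per[owner] += 1
                if any(per[name] > budgets[name] for name in per):
                    break
            else:
                raise ValueError(f"unknown missed_budget {missed_budget!r}")
            peptides.append(
                Peptide(protein_id, start + 1, end, sequence[start:end])
            )
    return peptides


# ---------------------------------------------------------------------------
# masses


def peptide_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass: residues + water + fixed/variable mods."""
    total = WATER
    for aa in p.sequence:
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise MassError(f"no monoisotopic mass for residue {aa!r}") from None
        if aa == "C":
            total += CARBAMIDOMETHYL
    for _pos, name in p.var_mods:
        if name != "ox":
            raise MassError(f"unknown modification {name!r}")
        total += OXIDATION
    return total


def pair_mass(c: XLCandidate, registry: dict[str, LinkerSpec] | None = None) -> float:
    """Neutral monoisotopic mass of a cross-linked pair:
    ``mass(alpha) + mass(beta) + bridge`` (photo pairs: net N2 loss)."""
    linker = linkerchem.get_linker(c.linker_name, registry)
    _validate_chemistry(c, linker)
    return peptide_mass(c.alpha) + peptide_mass(c.beta) + linkerchem.bridge_mass(linker)


def _validate_chemistry(c: XLCandidate, linker: LinkerSpec) -> None:
    aa_a = c.alpha.sequence[c.link_pos_alpha - c.alpha.start]
    aa_b = c.beta.sequence[c.link_pos_beta - c.beta.start]
    if linker.photo:
        if aa_a not in linker.photo_residues and aa_b not in linker.photo_residues:
            raise linkerchem.ChemistryError(
                f"photo pair requires a photo residue, got {aa_a!r}/{aa_b!r}"
            )
        return
    for aa, pos in ((aa_a, c.link_pos_alpha), (aa_b, c.link_pos_beta)):
        # the protein N-terminal amine is a valid site regardless of residue
        if pos == 1 and N_TERMINUS in linker.reactive_targets:
            continue
        if aa not in linker.reactive_targets:
            raise linkerchem.ChemistryError(
                f"{linker.name} does not react with {aa!r} at position {pos}"
            )


def enumerate_candidates(
    peptides_a: list[Peptide],
    peptides_b: list[Peptide],
    linker_name: str,
    registry: dict[str, LinkerSpec] | None = None,
) -> list[XLCandidate]:
    """All candidate pairs with chemically valid link-site combinations."""
    linker = linkerchem.get_linker(linker_name, registry)
    out = []
    for pa, pb in itertools.product(peptides_a, peptides_b):
        for ia, aa_a in enumerate(pa.sequence):
            for ib, aa_b in enumerate(pb.sequence):
                cand = XLCandidate(
                    pa, pb, pa.start + ia, pb.start + ib, linker_name
                )
                try:
                    _validate_chemistry(cand, linker)
                except linkerchem.ChemistryError:
                    continue
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# precursor matching


@dataclass(frozen=True)
class PrecursorMatch:
    observation_index: int
    candidate: XLCandidate
    observed_neutral: float
    ppm: float


def neutral_mass(mz: float, charge: int) -> float:
    """Neutral mass from an (m/z, z) observation."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz * charge - charge * PROTON


def match_precursors(
    observations: list[tuple[float, int]],
    candidates: list[XLCandidate],
    ppm_max: float = 3.0,
    registry: dict[str, LinkerSpec] | None = None,
) -> list[PrecursorMatch]:
    """Match observed precursors to candidates within ``ppm_max`` (inclusive).

    Returns every qualifying (observation, candidate) pair, sorted by
    absolute ppm error (then observation index).
    """
    if ppm_max <= 0:
        raise ValueError("ppm_max must be > 0")
    theo = [pair_mass(c, registry) for c in candidates]
    matches = []
    for oi, (mz, z) in enumerate(observations):
        obs = neutral_mass(mz, z)
        for c, t in zip(candidates, theo):
            ppm = (obs - t) / t * 1e6
            if abs(ppm) <= ppm_max:
                matches.append(PrecursorMatch(oi, c, obs, ppm))
    return sorted(matches, key=lambda m: (abs(m.ppm), m.observation_index))


def snr_filter(matches: list[PrecursorMatch]) -> list[PrecursorMatch]:
    """Hook for spectrum-level signal-to-noise filtering.

    Raw spectra are outside this package's scope, so this is a no-op kept
    to mark where an S/N >= 2 gate would apply in a full pipeline.
    """
    return list(matches)


# ---------------------------------------------------------------------------
# fragment ions


@dataclass(frozen=True)
class FragmentIon:
    peptide: str  # "alpha" or "beta"
    series: str  # "b" or "y"
    index: int
    mz: float  # singly protonated
    contains_link: bool
    neutral_loss: str = ""  # "", "-H2O", "-NH3"


_H2O = WATER
_NH3 = _pmass.calculate_mass(formula="NH3")


def _residue_masses(p: Peptide) -> list[float]:
    masses = []
    mods = dict((pos, name) for pos, name in p.var_mods)
    for i, aa in enumerate(p.sequence):
        m = RESIDUE_MASSES[aa]
        if aa == "C":
            m += CARBAMIDOMETHYL
        if mods.get(p.start + i) == "ox":
            m += OXIDATION
        masses.append(m)
    return masses


def fragment_ions(
    c: XLCandidate,
    series: tuple = ("b", "y"),
    neutral_losses: bool = False,
    registry: dict[str, LinkerSpec] | None = None,
) -> list[FragmentIon]:
    """Theoretical singly-protonated b/y fragments of both peptides.

    b1 ions are excluded (conventionally unobserved); y1 is included.
    Fragments spanning the link site carry the partner peptide plus the
    bridge mass.  With ``neutral_losses`` the -H2O and -NH3 variants are
    added for every ion.
    """
    linker = linkerchem.get_linker(c.linker_name, registry)
    bridge = linkerchem.bridge_mass(linker)
    out: list[FragmentIon] = []
    partners = {
        "alpha": (c.alpha, c.link_pos_alpha, peptide_mass(c.beta)),
        "beta": (c.beta, c.link_pos_beta, peptide_mass(c.alpha)),
    }
    for label, (pep, link_pos, partner_mass) in partners.items():
        res = _residue_masses(pep)
        n = len(res)
        link_idx = link_pos - pep.start  # 0-based
        for i in range(1, n):
            if "b" in series and i >= 2:
                m = sum(res[:i]) + PROTON
                has_link = link_idx < i
                if has_link:
                    m += partner_mass + bridge
                out.append(FragmentIon(label, "b", i, m, has_link))
            if "y" in series:
                m = sum(res[n - i :]) + WATER + PROTON
                has_link = link_idx >= n - i
                if has_link:
                    m += partner_mass + bridge
                out.append(FragmentIon(label, "y", i, m, has_link))
    if neutral_losses:
        variants = []
        for ion in out:
            variants.append(
                FragmentIon(ion.peptide, ion.series, ion.index, ion.mz - _H2O,
                            ion.contains_link, "-H2O")
            )
            variants.append(
                FragmentIon(ion.peptide, ion.series, ion.index, ion.mz - _NH3,
                            ion.contains_link, "-NH3")
            )
        out.extend(variants)
    return out
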