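"""Synthetic-data generators with planted ground truth.

Every input class the pipeline consumes can be generated here with known
truth, so each stage is testable without downloads: compact polypeptide
Calpha traces and two-chain complexes, cross-link sets with controlled
satisfied/tolerated/violated fractions, model ensembles with planted
clusters, precursor observations with controlled ppm error, and noisy
single-cycle sensorgrams.  All generators are deterministic under a fixed
seed.

Synthetic chains carry Lys/Leu/Met-rich sequences so both the
amine-reactive and the photo chemistry have abundant reactive sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from xlms import linkerchem
from xlms.bindingaffinity import (
    InjectionSchedule,
    KineticParams,
    simulate_sck,
    single_cycle_schedule,
)
from xlms.digestmatch import PROTON, XLCandidate, pair_mass
from xlms.ensembletools import ModelRecord
from xlms.structio import (
    ResidueEntry,
    ResidueRef,
    StructureModel,
    one_letter,
    three_letter,
)
from xlms.xlinkmap import CrossLink


class GenerationError(RuntimeError):
    """A generator could not satisfy its constraints (e.g. walk failure)."""


# Lys/Leu/Met-rich repeat used for synthetic chain sequences
_SEQ_MOTIF = "KLKMKE"


def default_sequence(n: int) -> str:
    return (_SEQ_MOTIF * (n // len(_SEQ_MOTIF) + 1))[:n]


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset: a kind, its
    parameters, and the seed.  Identical spec + seed gives identical
    output."""

    kind: str  # chain | complex | crosslink_set | ensemble | precursor_set | sensorgram
    parameters: tuple  # sorted (name, value) pairs
    seed: int

    @classmethod
    def make(cls, kind: str, seed: int, **parameters) -> "GeneratorSpec":
        return cls(kind, tuple(sorted(parameters.items())), seed)


def _chain_entries(coords: np.ndarray, sequence: str, start_resnum: int = 1):
    return [
        ResidueEntry(start_resnum + i, "", three_letter(aa), coords[i])
        for i, aa in enumerate(sequence)
    ]


def _helix_coords(n: int) -> np.ndarray:
    # 1.5 A rise and 100 degrees per residue on a 2.3 A radius: consecutive
    # Calpha atoms end up ~3.8 A apart, as in an alpha helix
    theta = np.deg2rad(100.0) * np.arange(n)
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)]
    )


def _extended_coords(n: int) -> np.ndarray:
    return np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])


def _compact_walk(n: int, rng: np.random.Generator, max_restarts: int = 200) -> np.ndarray:
    """Self-avoiding walk with 3.8 A steps, >= 4.0 A non-bonded separation,
    biased toward the origin to yield a compact globule."""
    for _restart in range(max_restarts):
        coords = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            candidates = rng.normal(size=(40, 3))
            candidates /= np.linalg.norm(candidates, axis=1, keepdims=True)
            trial = coords[-1] + 3.8 * candidates
            arr = np.array(coords)
            valid = []
            for pos in trial:
                if len(arr) < 2:
                    valid.append(pos)
                    continue
                d = np.linalg.norm(arr[:-1] - pos, axis=1)
                if np.all(d >= 4.0):
                    valid.append(pos)
            if not valid:
                ok = False
                break
            valid = np.array(valid)
            if rng.random() < 0.3:
                # compactness bias: prefer the candidate closest to the centroid
                centroid = arr.mean(axis=0)
                pick = valid[np.argmin(np.linalg.norm(valid - centroid, axis=1))]
            else:
                pick = valid[rng.integers(len(valid))]
            coords.append(pick)
            placed = True
            if not placed:  # pragma: no cover - defensive
                ok = False
                break
        if ok:
            return np.array(coords)
    raise GenerationError(f"self-avoiding walk failed after {max_restarts} restarts")


def gen_chain(
    n_residues: int,
    geometry: str = "compact_random",
    seed: int = 0,
    sequence: str | None = None,
    chain_id: str = "A",
    model_id: str | None = None,
) -> StructureModel:
    """Synthetic single-chain Calpha trace.

    ``geometry``: ``helix`` (1.5 A rise, 100 deg/residue, 2.3 A radius),
    ``extended`` (3.8 A spacing on a line), or ``compact_random``
    (origin-biased self-avoiding walk, 3.8 A steps, >= 4.0 A non-bonded
    separation).
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    sequence = sequence or default_sequence(n_residues)
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    rng = np.random.default_rng(seed)
    if geometry == "helix":
        coords = _helix_coords(n_residues)
    elif geometry == "extended":
        coords = _extended_coords(n_residues)
    elif geometry == "compact_random":
        coords = _compact_walk(n_residues, rng)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    model = StructureModel(model_id or f"synthetic-{geometry}-{seed}")
    model.chains[chain_id] = _chain_entries(coords, sequence)
    return model


def gen_complex(
    n_a: int,
    n_b: int,
    seed: int = 0,
    separation: float = 20.0,
    geometry: str = "compact_random",
) -> StructureModel:
    """Two-chain synthetic complex: chains A and B, centers of mass
    ``separation`` Angstrom apart along x."""
    rng = np.random.default_rng(seed)
    a = gen_chain(n_a, geometry, int(rng.integers(2**31)), chain_id="A")
    b = gen_chain(n_b, geometry, int(rng.integers(2**31)), chain_id="B")
    coords_b = np.array([e.ca for e in b.chains["B"]])
    coords_a = np.array([e.ca for e in a.chains["A"]])
    shift = coords_a.mean(axis=0) - coords_b.mean(axis=0) + np.array([separation, 0, 0])
    model = StructureModel(f"synthetic-complex-{seed}")
    model.chains["A"] = a.chains["A"]
    model.chains["B"] = [
        ResidueEntry(e.resnum, e.icode, e.resname, e.ca + shift) for e in b.chains["B"]
    ]
    return model


def gen_crosslink_set(
    structure: StructureModel,
    linker_name: str = "BS2G",
    n_within: int = 3,
    n_tolerated: int = 3,
    n_violated: int = 3,
    seed: int = 0,
    protein_id: str = "synthetic",
    chain_id: str = "A",
) -> tuple[list[CrossLink], pd.DataFrame]:
    """Sample reactive residue pairs whose true distances fall in the
    three satisfaction bands of the linker's bound ladder.

    Bands: within ``[0, bound_none]``, tolerated ``(bound_none, bound_md]``,
    violated ``(bound_md, inf)``.  Returns the links plus a planted-truth
    table (pair, distance, expected status).  Raises
    :class:`GenerationError` when the structure lacks enough pairs in a
    requested band.
    """
    rng = np.random.default_rng(seed)
    linker = linkerchem.get_linker(linker_name)
    entries = structure.chain(chain_id)
    if linker.photo:
        photo_code = sorted(linker.photo_residues)[0]
        reactive_a = [
            e for e in entries if one_letter(e.resname) in (photo_code, "L", "M")
        ]
        reactive_b = entries
    else:
        reactive_a = reactive_b = [
            e for e in entries if one_letter(e.resname) in linker.reactive_targets
        ]
    pairs_by_band: dict[str, list] = {"within": [], "tolerated": [], "violated": []}
    seen = set()
    for ea in reactive_a:
        for eb in reactive_b:
            if ea.resnum >= eb.resnum or ea.ca is None or eb.ca is None:
                continue
            key = (ea.resnum, eb.resnum)
            if key in seen:
                continue
            seen.add(key)
            aa_a = photo_code if linker.photo else one_letter(ea.resname)
            aa_b = one_letter(eb.resname)
            try:
                b_none = linkerchem.max_ca_distance(linker, aa_a, aa_b, "none")
                b_md = linkerchem.max_ca_distance(linker, aa_a, aa_b, "md")
            except (linkerchem.ChemistryError, linkerchem.RegistryError):
                continue
            d = float(np.linalg.norm(ea.ca - eb.ca))
            if d <= b_none:
                band = "within"
            elif d <= b_md:
                band = "tolerated"
            else:
                band = "violated"
            pairs_by_band[band].append((ea, eb, aa_a, aa_b, d))
    wanted = {"within": n_within, "tolerated": n_tolerated, "violated": n_violated}
    links: list[CrossLink] = []
    truth_rows = []
    k = 0
    for band, n in wanted.items():
        pool = pairs_by_band[band]
        if len(pool) < n:
            raise GenerationError(
                f"structure offers only {len(pool)} candidate pairs in band "
                f"{band!r}, {n} requested"
            )
        for i in rng.choice(len(pool), size=n, replace=False):
            ea, eb, aa_a, aa_b, d = pool[int(i)]
            k += 1
            links.append(
                CrossLink(
                    id=f"xl{k}",
                    site_a=ResidueRef(protein_id, ea.resnum, aa_a),
                    site_b=ResidueRef(protein_id, eb.resnum, aa_b),
                    linker_name=linker_name,
                )
            )
            truth_rows.append(
                {
                    "id": f"xl{k}", "pos_a": ea.resnum, "pos_b": eb.resnum,
                    "distance": d, "planted_status": band,
                }
            )
    return links, pd.DataFrame(truth_rows)


def gen_redundant_observations(
    base_links: list[CrossLink],
    n_total: int,
    seed: int = 0,
) -> list[CrossLink]:
    """Expand non-redundant links into ``n_total`` observations by
    duplicating random pairs (distinct peptide forms of the same residue
    pair), mirroring how redundant MS observations collapse back to the
    planted pair count."""
    if n_total < len(base_links):
        raise ValueError("n_total must be >= number of base links")
    rng = np.random.default_rng(seed)
    observations = []
    for i, xl in enumerate(base_links):
        observations.append(
            CrossLink(f"obs{i}", xl.site_a, xl.site_b, xl.linker_name)
        )
    for j in range(n_total - len(base_links)):
        xl = base_links[int(rng.integers(len(base_links)))]
        # swap sites: the canonicalization in CrossLink restores order
        observations.append(
            CrossLink(f"obs-dup{j}", xl.site_b, xl.site_a, xl.linker_name)
        )
    return observations


def gen_ensemble(
    base: StructureModel | np.ndarray,
    k_clusters: int = 2,
    spread_rmsd: float = 0.5,
    n_per_cluster: int = 5,
    seed: int = 0,
    between_sd: float = 10.0,
    chain_id: str = "A",
) -> tuple[list[ModelRecord], dict[str, int]]:
    """Model ensemble with planted clusters.

    Cluster centers are independent large coordinate perturbations (sd
    ``between_sd`` per coordinate) plus random rigid moves of the base;
    members jitter their center with expected unaligned RMSD of about
    ``spread_rmsd``.  Returns the models and the planted label per model
    id.  Requires the between-cluster spread to dominate the within
    spread.
    """
    if between_sd < 5 * spread_rmsd:
        raise ValueError("between-cluster spread must dominate within-cluster spread")
    rng = np.random.default_rng(seed)
    if isinstance(base, StructureModel):
        coords = np.array([e.ca for e in base.chain(chain_id) if e.ca is not None])
    else:
        coords = np.asarray(base, dtype=float)
    member_sd = spread_rmsd / np.sqrt(3.0)
    models: list[ModelRecord] = []
    labels: dict[str, int] = {}
    from scipy.spatial.transform import Rotation

    for k in range(k_clusters):
        # a random rigid move (invisible to superposed RMSD) plus a large
        # coordinate deformation that separates the clusters
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.normal(0.0, 20.0, size=3)
        center = coords @ rot.T + shift + rng.normal(0.0, between_sd, size=coords.shape)
        for m in range(n_per_cluster):
            jitter = rng.normal(0.0, member_sd, size=coords.shape)
            mid = f"c{k}m{m}"
            models.append(
                ModelRecord(mid, center + jitter, source_tag=f"centroid{k}")
            )
            labels[mid] = k
    return models, labels


def gen_precursors(
    candidates: list[XLCandidate],
    ppm_error_range: float = 5.0,
    match_fraction: float = 0.5,
    seed: int = 0,
    ppm_gate: float = 3.0,
) -> tuple[list[tuple[float, int]], pd.DataFrame]:
    """Precursor observations with controlled ppm error.

    A ``match_fraction`` share of candidates receives an injected error
    uniform in ``[-ppm_gate, ppm_gate]`` (matchable); the rest get
    ``|error|`` uniform in ``(ppm_gate, ppm_error_range]``.  Charges are
    sampled from 2-4.  Returns (m/z, charge) observations and a truth
    table with the injected error per candidate.
    """
    if not candidates:
        raise ValueError("no candidates given")
    if ppm_error_range <= ppm_gate and match_fraction < 1.0:
        raise ValueError("ppm_error_range must exceed the gate to plant non-matches")
    rng = np.random.default_rng(seed)
    n = len(candidates)
    n_match = int(round(match_fraction * n))
    is_match = np.zeros(n, dtype=bool)
    is_match[rng.choice(n, size=n_match, replace=False)] = True
    observations = []
    rows = []
    for i, cand in enumerate(candidates):
        theo = pair_mass(cand)
        if is_match[i]:
            eps = rng.uniform(-ppm_gate, ppm_gate)
        else:
            mag = rng.uniform(np.nextafter(ppm_gate, np.inf), ppm_error_range)
            eps = mag if rng.random() < 0.5 else -mag
        observed = theo * (1.0 + eps * 1e-6)
        z = int(rng.integers(2, 5))
        observations.append(((observed + z * PROTON) / z, z))
        rows.append(
            {
                "candidate_index": i, "theo_mass": theo, "injected_ppm": eps,
                "charge": z, "is_match": bool(abs(eps) <= ppm_gate),
            }
        )
    return observations, pd.DataFrame(rows)


def gen_sensorgram(
    params: KineticParams | None = None,
    sched: InjectionSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_hz: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, KineticParams, InjectionSchedule]:
    """Noisy single-cycle sensorgram with known truth.

    Defaults emulate a nanomolar-affinity interaction probed by five
    1-min injections (6.25-100 nM) with 40.6-min dissociation gaps:
    ka = 1e6 /(M s), kd = 1e-3 /s (Kd = 1 nM), Rmax = 100 RU.
    Returns (times, response, true params, schedule).
    """
    params = params or KineticParams(ka=1e6, kd=1e-3, rmax=100.0)
    sched = sched or single_cycle_schedule()
    last_conc, last_start, last_dur = sched.injections[-1]
    t_end = last_start + last_dur + 2436.0
    times = np.arange(0.0, t_end, 1.0 / sample_hz)
    response = simulate_sck(params, sched, times, noise_sd=noise_sd, seed=seed)
    return times, response, params, sched


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to its generator function."""
    params = dict(spec.parameters)
    dispatch = {
        "chain": gen_chain,
        "complex": gen_complex,
        "crosslink_set": gen_crosslink_set,
        "ensemble": gen_ensemble,
        "precursor_set": gen_precursors,
        "sensorgram": gen_sensorgram,
    }
    try:
        fn = dispatch[spec.kind]
    except KeyError:
        raise ValueError(f"unknown generator kind {spec.kind!r}") from None
    return fn(seed=spec.seed, **params)


def gen_distance_embedding(
    targets: list,
    seed: int = 0,
    tol: float = 1e-8,
    max_restarts: int = 20,
) -> StructureModel:
    """Synthetic stand-in structure realizing a set of pairwise distances.

    ``targets`` is a list of ``(CrossLink, distance)`` pairs; the sites'
    residues are embedded in 3D by least squares so that every listed
    Calpha-Calpha distance is met (to ``tol`` in summed squared error).
    Each protein id becomes its own chain (A, B, ... in sorted protein
    order) holding only the referenced residues.  This is a synthetic
    reconstruction from printed distances, not an experimental structure:
    unconstrained geometry (and every non-listed pair distance) is
    arbitrary.
    """
    from scipy import optimize

    refs: dict[tuple, ResidueRef] = {}
    for xl, _d in targets:
        for ref in (xl.site_a, xl.site_b):
            refs.setdefault(ref.key, ref)
    keys = sorted(refs)
    index = {k: i for i, k in enumerate(keys)}
    pairs = np.array(
        [[index[xl.site_a.key], index[xl.site_b.key]] for xl, _d in targets]
    )
    dists = np.array([d for _xl, d in targets], dtype=float)
    rng = np.random.default_rng(seed)

    def residuals(flat):
        x = flat.reshape(-1, 3)
        cur = np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)
        return cur - dists

    best = None
    for _ in range(max_restarts):
        x0 = rng.normal(0.0, dists.max() / 2.0, size=(len(keys), 3)).ravel()
        res = optimize.least_squares(residuals, x0)
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < tol:
            break
    if best.cost >= tol:
        raise GenerationError(
            f"distance embedding did not converge (residual cost {best.cost:.3g})"
        )
    coords = best.x.reshape(-1, 3)
    proteins = sorted({k[0] for k in keys})
    chain_of = {p: chr(ord("A") + i) for i, p in enumerate(proteins)}
    model = StructureModel(f"synthetic-embedding-{seed}")
    for p in proteins:
        model.chains[chain_of[p]] = [
            ResidueEntry(k[1], "", three_letter(refs[k].aa), coords[index[k]])
            for k in keys
            if k[0] == p
        ]
    return model
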