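import csv
from pathlib import Path

import pytest

from xlms import structio, synthetic_data, xlinkmap

REPO_ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = REPO_ROOT / "data"


def _pdb_line(serial, resname, chain, resnum, x, y, z, name=" CA "):
    return (
        f"ATOM  {serial:5d} {name:4s} {resname:<3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{name.strip()[0]:>2s}\n"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 3-residue chain with Calpha at 0 / 3.8 / 7.6 on x."""
    text = (
        _pdb_line(1, "ALA", "A", 1, 0.0, 0.0, 0.0)
        + _pdb_line(2, "GLY", "A", 2, 3.8, 0.0, 0.0)
        + _pdb_line(3, "LYS", "A", 3, 7.6, 0.0, 0.0)
        + "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def missing_ca_pdb(tmp_path):
    """Middle residue carries only a backbone nitrogen, no CA record."""
    text = (
        _pdb_line(1, "ALA", "A", 1, 0.0, 0.0, 0.0)
        + _pdb_line(2, "GLY", "A", 2, 3.8, 0.0, 0.0, name=" N  ")
        + _pdb_line(3, "LYS", "A", 3, 7.6, 0.0, 0.0)
        + "END\n"
    )
    path = tmp_path / "gap.pdb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def compact_chain():
    """150-residue Lys-rich self-avoiding-walk chain (deterministic)."""
    return synthetic_data.gen_chain(150, "compact_random", seed=11)


@pytest.fixture(scope="session")
def compact_chain_map(compact_chain):
    return {"synthetic": structio.identity_map(compact_chain, "A", "synthetic")}


@pytest.fixture(scope="session")
def published_link_table():
    """The 13 cross-links of the nidogen-1 G3/laminin LEb2-4 complex with
    their published crystal-structure Calpha-Calpha distances."""
    path = DATA_DIR / "crosslinks_g3_leb24.tsv"
    links = xlinkmap.read_crosslinks(path)
    with open(path) as fh:
        ref = {
            row["id"]: float(row["ca_dist_reference"])
            for row in csv.DictReader(fh, delimiter="\t")
        }
    return links, ref
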