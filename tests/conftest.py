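import numpy as np
import pytest

from ligsieve import fixtures, mmcif_model


@pytest.fixture
def parse_builder(tmp_path):
    """Write a CifBuilder to disk and parse it back through the real parser."""
    def _parse(builder: fixtures.CifBuilder) -> mmcif_model.Structure:
        path = tmp_path / f"{builder.pdb_id}.cif"
        builder.write(path)
        return mmcif_model.parse_mmcif(path)
    return _parse


@pytest.fixture(scope="session")
def scenario_factory(tmp_path_factory):
    """Generate (and cache) fixture scenarios for the whole session."""
    cache: dict[tuple[str, int], fixtures.ScenarioBundle] = {}

    def _get(scenario_id: str, seed: int = 0) -> fixtures.ScenarioBundle:
        key = (scenario_id, seed)
        if key not in cache:
            d = tmp_path_factory.mktemp(f"scen_{scenario_id}_{seed}")
            cache[key] = fixtures.generate_scenario(scenario_id, d, seed=seed)
        return cache[key]

    return _get


def simple_protein_ligand_builder(pdb_id="tst1", lig_code="LIG",
                                  lig_atoms=8, resolutions=(1.8,)):
    """One 20-residue query helix plus one HETATM small molecule."""
    b = fixtures.CifBuilder(pdb_id, resolutions)
    cas = fixtures._standard_protein(b)
    b.add_entity("2", "non-polymer", "syn", "test ligand")
    center = fixtures._surface_point(cas[10], 4.0)
    b.add_residue("HETATM", lig_code, "B", 1,
                  fixtures.blob_atoms(center, lig_atoms), "2")
    return b


def union_find_components(nodes, edges):
    """Independent connected-components oracle (union-find)."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((frozenset(c) for c in comps.values()), key=sorted)


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Horn's closed-form quaternion solution for minimal RMSD.

    Independent oracle for the SVD-based superposition: the optimal
    rotation's quality comes from the largest eigenvalue of the 4x4
    quaternion matrix, with no shared code path.
    """
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    s = m.T @ r
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    resid = (m ** 2).sum() + (r ** 2).sum() - 2.0 * lam
    return float(np.sqrt(max(resid, 0.0) / len(m)))
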