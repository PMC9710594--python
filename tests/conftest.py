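import numpy as np
import pytest

from codes.structure_io import Atom, ComplexModel
from codes.synthetic import SyntheticSpec, make_decoys, make_native


def make_atom(serial, coords, name="CA", element="C", res_name="ALA",
              chain="A", resseq=1, icode=""):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=res_name,
        chain_id=chain,
        residue_seq=resseq,
        insertion_code=icode,
        coords=np.asarray(coords, dtype=float),
        is_hydrogen=element.upper() in ("H", "D"),
    )


def two_atom_complex(distance, element="C"):
    """Minimal complex: one receptor atom at origin, one ligand atom at x=d."""
    atoms = [
        make_atom(1, [0, 0, 0], chain="A", resseq=1, element=element),
        make_atom(2, [distance, 0, 0], chain="B", resseq=1, element=element),
    ]
    return ComplexModel("m", "t", atoms, frozenset("A"), frozenset("B"))


def random_complex(rng, n_rec=20, n_lig=10, spread=15.0):
    """Random atom cloud split into two bodies; used against brute-force oracles."""
    atoms = []
    serial = 0
    for i in range(n_rec):
        serial += 1
        atoms.append(make_atom(serial, rng.uniform(-spread, spread, 3),
                               chain="A", resseq=i + 1))
    for i in range(n_lig):
        serial += 1
        atoms.append(make_atom(serial, rng.uniform(-spread, spread, 3),
                               chain="B", resseq=i + 1))
    return ComplexModel("rand", "t", atoms, frozenset("A"), frozenset("B"))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_contacts(model, cutoff):
    """O(N^2) double loop over heavy-atom pairs (oracle)."""
    rec = model.body_atoms("receptor", heavy_only=True)
    lig = model.body_atoms("ligand", heavy_only=True)
    pairs = set()
    for a in rec:
        for b in lig:
            if np.linalg.norm(a.coords - b.coords) < cutoff:
                pairs.add((a.residue_key, b.residue_key))
    return pairs


def brute_force_interface(model, cutoff):
    rec = model.body_atoms("receptor", heavy_only=True)
    lig = model.body_atoms("ligand", heavy_only=True)
    out = set()
    for a in rec:
        for b in lig:
            if np.linalg.norm(a.coords - b.coords) < cutoff:
                out.add(a.residue_key)
                out.add(b.residue_key)
    return out


def brute_force_clashes(model, cutoff):
    rec = model.body_atoms("receptor", heavy_only=True)
    lig = model.body_atoms("ligand", heavy_only=True)
    n = 0
    for a in rec:
        for b in lig:
            if np.linalg.norm(a.coords - b.coords) < cutoff:
                n += 1
    return n


def quaternion_superpose_rmsd(mobile, reference):
    """Horn quaternion-based optimal superposition RMSD (oracle for Kabsch)."""
    p = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    q = np.asarray(reference, float) - np.mean(reference, axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigenvalues = np.linalg.eigvalsh(k)
    lam = eigenvalues[-1]
    e = float(np.sum(p ** 2) + np.sum(q ** 2) - 2.0 * lam)
    return np.sqrt(max(e, 0.0) / len(p))


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# shared fixtures


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def native(default_spec):
    return make_native(default_spec, 0)


@pytest.fixture(scope="session")
def decoy_ensemble(default_spec, native):
    decoys, tiers = make_decoys(native, default_spec)
    return decoys, tiers
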