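"""Synthetic fixtures: toy structures, ideal tripeptides, simulated
alignments with planted site rates, and an end-to-end variant benchmark.

Every generator is a pure function of its spec plus a seed: one root seed
is split into per-component substreams with ``numpy.random.SeedSequence``,
so outputs are reproducible and components are decoupled.

Peptide geometry: backbones are built atom-by-atom with the NeRF internal-
coordinate construction (standard bond lengths N-CA 1.458 Å, CA-C 1.525 Å,
C-N 1.329 Å and angles), at caller-chosen phi/psi; full residues are then
completed by rigidly superimposing each residue's ideal-coordinate heavy
atoms from the Chemical Component Dictionary (bundled with biotite) onto
the built backbone frame.  Side chains therefore sit in the CCD's ideal
rotamer — adequate for surface-area work, not for chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import biotite.structure.info as _ccd
import numpy as np
import pandas as pd

from .aa import AA_ORDER, ONE_TO_THREE, STANDARD_RESIDUES
from .conservation import Msa, PhyloTree, PoissonModel
from .errors import GenerationError, LookupFailure, ParameterError
from .structure_io import Atom, ResidueId, Structure

__all__ = [
    "make_tripeptide",
    "make_peptide",
    "ToyFoldSpec",
    "make_toy_fold",
    "SimAlignmentSpec",
    "simulate_alignment",
    "balanced_tree",
    "make_variant_benchmark",
    "VariantBenchmark",
]

# ideal backbone internal coordinates (Engh & Huber style values)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom d with |cd| = bond, angle(b,c,d) and torsion
    (a,b,c,d) as given."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation + translation minimising RMSD of mobile onto target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def _ideal_residue(resname: str) -> tuple[list[str], list[str], np.ndarray]:
    """Heavy-atom names, elements and ideal CCD coordinates for a residue
    (terminal OXT dropped)."""
    resname = resname.upper()
    if resname not in STANDARD_RESIDUES:
        raise LookupFailure(f"nonstandard residue {resname!r}")
    arr = _ccd.residue(resname)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    arr = arr[keep]
    return list(arr.atom_name), list(arr.element), np.asarray(arr.coord, dtype=float)


def _backbone(n_res: int, phi: float, psi: float, omega: float = 180.0) -> list[dict]:
    """Backbone N/CA/C/O positions for an ideal-geometry chain."""
    residues: list[dict] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = residues[-1]
        n_next = _place(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = _place(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANGLE_C_N_CA, omega)
        c_next = _place(prev["C"], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl oxygens: anti to the next residue's N (psi + 180)
    for i, res in enumerate(residues):
        res["O"] = _place(res["N"], res["CA"], res["C"], _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0)
    return residues


def _residue_atoms(
    resname: str, backbone: dict, rid: ResidueId
) -> list[Atom]:
    """Complete one residue: CCD ideal heavy atoms superimposed on the
    built N/CA/C frame; backbone N/CA/C taken exactly from the frame."""
    names, elements, coords = _ideal_residue(resname)
    idx = {n: i for i, n in enumerate(names)}
    for req in ("N", "CA", "C"):
        if req not in idx:
            raise GenerationError(f"CCD template {resname} lacks backbone atom {req}")
    mobile = coords[[idx["N"], idx["CA"], idx["C"]]]
    target = np.vstack([backbone["N"], backbone["CA"], backbone["C"]])
    rot, trans = _kabsch(mobile, target)
    placed = coords @ rot.T + trans
    exact = {"N": backbone["N"], "CA": backbone["CA"], "C": backbone["C"],
             "O": backbone["O"]}
    atoms = []
    for name, element, xyz in zip(names, elements, placed):
        pos = exact.get(name, xyz)
        atoms.append(
            Atom(
                name=name,
                element=element.upper(),
                coords=tuple(float(v) for v in pos),
                residue_name=resname,
                residue=rid,
            )
        )
    return atoms


def _as_three_letter(code: str) -> str:
    code = code.upper()
    if len(code) == 1:
        if code not in ONE_TO_THREE:
            raise LookupFailure(f"unknown residue code {code!r}")
        return ONE_TO_THREE[code]
    return code


def make_peptide(
    sequence: Sequence[str],
    phi: float = -120.0,
    psi: float = 120.0,
    chain: str = "A",
    first_number: int = 1,
    structure_id: str = "peptide",
) -> Structure:
    """Ideal-geometry peptide at uniform (phi, psi); deterministic."""
    if not -180.0 < phi <= 180.0 or not -180.0 < psi <= 180.0:
        raise ParameterError("phi/psi must lie in (-180, 180]")
    seq3 = [_as_three_letter(r) for r in sequence]
    backbone = _backbone(len(seq3), phi, psi)
    atoms: list[Atom] = []
    for i, (resname, bb) in enumerate(zip(seq3, backbone)):
        rid = ResidueId(chain, first_number + i)
        atoms.extend(_residue_atoms(resname, bb, rid))
    return Structure(atoms=atoms, id=structure_id)


def make_tripeptide(x: str, phi: float = -120.0, psi: float = 120.0) -> Structure:
    """Extended Gly-X-Gly tripeptide, the reference state for relative
    solvent accessibility."""
    x3 = _as_three_letter(x)
    return make_peptide(["GLY", x3, "GLY"], phi, psi, structure_id=f"GXG-{x3}")


# ---------------------------------------------------------------------------
# toy folds with known burial


@dataclass(frozen=True)
class ToyFoldSpec:
    """Specification of a synthetic structure with known burial labels.

    packing 'compact-shell' buries residue 1 at the centroid of a shell of
    small residues; 'extended' and 'helix' are open chains where every
    residue stays exposed.
    """

    n_residues: int = 20
    center_residue: str = "ALA"
    shell_residue: str = "GLY"
    packing: str = "compact-shell"
    seed: int = 0
    first_number: int = 1
    structure_id: str = ""

    def resolved_id(self) -> str:
        return self.structure_id or f"toyfold-{self.packing}-s{self.seed}"


_SHELL_RADII = (5.6, 8.4)  # Å; inner shell occludes, outer takes overflow
_MIN_HEAVY_DIST = 2.0  # clash-light constraint
_MAX_RETRIES = 50


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
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


def _radial_orientation(template: np.ndarray, direction: np.ndarray,
                        roll: float) -> np.ndarray:
    """Rotate centred template coords so their principal axis is radial,
    then roll about that axis; keeps lateral extent small so shell residues
    stay clash-free while their atoms span a range of radii."""
    centered = template - template.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered)
    axis = vt[0]
    # rotation taking `axis` onto `direction`
    v = np.cross(axis, direction)
    c = float(np.dot(axis, direction))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    cr, sr = np.cos(roll), np.sin(roll)
    d = direction
    k = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
    roll_rot = np.eye(3) + sr * k + (1 - cr) * (k @ k)
    return centered @ rot.T @ roll_rot.T


def _min_interresidue_distance(atoms: Sequence[Atom]) -> float:
    """Smallest heavy-atom distance between atoms of different,
    non-adjacent residues (bonded geometry within a residue and across a
    peptide bond is legitimately short)."""
    from scipy.spatial.distance import pdist, squareform

    pts = np.array([a.coords for a in atoms])
    keys = [(a.residue.chain, a.residue.number) for a in atoms]
    d = squareform(pdist(pts))
    n = len(atoms)
    mask = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if keys[i][0] == keys[j][0] and abs(keys[i][1] - keys[j][1]) <= 1:
                mask[i, j] = False
    return float(d[mask].min()) if mask.any() else np.inf


def make_toy_fold(spec: ToyFoldSpec) -> tuple[Structure, dict[ResidueId, str]]:
    """Generate a toy structure plus ground-truth burial labels.

    compact-shell: residue 1 sits at the origin, the rest on one or two
    concentric quasi-uniform shells oriented radially; by construction the
    centre is occluded from every direction (label 'buried') while shell
    residues keep free outward surface (label 'exposed').  Geometry is
    jittered from the seed and regenerated (bounded retries) until no
    heavy-atom pair is closer than 2.0 Å.
    """
    if spec.packing in ("extended", "helix"):
        phi, psi = (-120.0, 120.0) if spec.packing == "extended" else (-57.0, -47.0)
        st = make_peptide(
            [spec.center_residue] * spec.n_residues,
            phi,
            psi,
            first_number=spec.first_number,
            structure_id=spec.resolved_id(),
        )
        labels = {rid: "exposed" for rid, _n, _i in st.residues()}
        return st, labels
    if spec.packing != "compact-shell":
        raise ParameterError(f"unknown packing {spec.packing!r}")
    if spec.n_residues < 8:
        raise ParameterError("compact-shell needs n_residues >= 8")

    n_shell = spec.n_residues - 1
    n_inner = min(n_shell, 30)
    n_outer = n_shell - n_inner
    root = np.random.SeedSequence([spec.seed, 0x70F01D])
    for attempt, child in enumerate(root.spawn(_MAX_RETRIES)):
        rng = np.random.default_rng(child)
        atoms: list[Atom] = []
        labels: dict[ResidueId, str] = {}

        names, elements, coords = _ideal_residue(spec.center_residue)
        centered = coords - coords.mean(axis=0)
        rot = _random_rotation(rng)
        rid = ResidueId("A", spec.first_number)
        for nm, el, xyz in zip(names, elements, centered @ rot.T):
            atoms.append(Atom(nm, el.upper(), tuple(map(float, xyz)),
                              spec.center_residue, rid))
        labels[rid] = "buried"

        s_names, s_elements, s_coords = _ideal_residue(spec.shell_residue)
        placements = []
        for radius, count in ((_SHELL_RADII[0], n_inner), (_SHELL_RADII[1], n_outer)):
            if count == 0:
                continue
            dirs = _fibonacci_directions(count)
            dirs = dirs @ _random_rotation(rng).T
            for d in dirs:
                placements.append((radius, d))
        for k, (radius, d) in enumerate(placements):
            rid = ResidueId("A", spec.first_number + 1 + k)
            jitter = rng.normal(scale=0.15, size=3)
            center = radius * d + jitter
            local = _radial_orientation(s_coords, d, rng.uniform(0, 2 * np.pi))
            for nm, el, xyz in zip(s_names, s_elements, local + center):
                atoms.append(Atom(nm, el.upper(), tuple(map(float, xyz)),
                                  spec.shell_residue, rid))
            labels[rid] = "exposed"

        if _min_interresidue_distance(atoms) >= _MIN_HEAVY_DIST:
            return Structure(atoms=atoms, id=spec.resolved_id()), labels
    raise GenerationError(
        f"could not satisfy clash constraints after {_MAX_RETRIES} attempts"
    )


# ---------------------------------------------------------------------------
# sequence simulation


@dataclass
class SimAlignmentSpec:
    """Simulation of an alignment along a tree with per-site rate
    multipliers (given explicitly or drawn from a mean-1 gamma)."""

    tree: PhyloTree
    n_sites: int
    site_rates: np.ndarray | tuple[str, float] | None = None
    model: object = field(default_factory=PoissonModel)
    seed: int = 0


def _resolve_rates(spec: SimAlignmentSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.site_rates is None:
        return np.ones(spec.n_sites)
    if isinstance(spec.site_rates, tuple):
        kind, alpha = spec.site_rates
        if kind != "gamma":
            raise ParameterError(f"unknown rate law {kind!r}")
        return rng.gamma(shape=alpha, scale=1.0 / alpha, size=spec.n_sites)
    rates = np.asarray(spec.site_rates, dtype=float)
    if rates.shape != (spec.n_sites,):
        raise ParameterError("site_rates length must equal n_sites")
    if (rates < 0).any():
        raise ParameterError("site rates must be >= 0")
    return rates


def simulate_alignment(spec: SimAlignmentSpec) -> tuple[Msa, np.ndarray]:
    """Evolve sequences from the stationary distribution down the tree.

    Returns the leaf alignment and the true per-site rates.  For the
    Poisson model transitions are sampled with the closed-form
    stay-or-randomise rule; general models go through their transition
    matrices per unique rate value.
    """
    if spec.n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    tree, model = spec.tree, spec.model
    if tree.n_leaves < 3:
        raise ParameterError("tree must have >= 3 leaves")
    root_seq = np.random.SeedSequence([spec.seed, 0xA11C])
    rates_rng, evo_rng = (np.random.default_rng(s) for s in root_seq.spawn(2))
    rates = _resolve_rates(spec, rates_rng)
    n_states = model.n_states

    states: dict[int, np.ndarray] = {}
    states[tree.root] = evo_rng.choice(n_states, size=spec.n_sites, p=model.freqs)
    # preorder: parents before children
    for node in range(tree.n_nodes - 1, -1, -1):
        parent_states = states[node]
        for child, bl in tree.children[node]:
            t = bl * rates  # per-site elapsed time
            if isinstance(model, PoissonModel):
                stay = np.exp(-n_states / (n_states - 1) * t)
                u = evo_rng.random(spec.n_sites)
                randomised = evo_rng.choice(n_states, size=spec.n_sites)
                states[child] = np.where(u < stay, parent_states, randomised)
            else:
                out = np.empty(spec.n_sites, dtype=int)
                for r in np.unique(t):
                    mask = t == r
                    p = model.transition_matrix(float(r))
                    for s in np.unique(parent_states[mask]):
                        sel = mask & (parent_states == s)
                        out[sel] = evo_rng.choice(
                            n_states, size=int(sel.sum()), p=p[s]
                        )
                states[child] = out

    ids, seqs = [], []
    for label in tree.leaf_labels:
        codes = states[tree.leaf_index[label]]
        ids.append(label)
        seqs.append("".join(AA_ORDER[c] for c in codes))
    return Msa(ids, seqs), rates


def balanced_tree(n_leaves: int, branch_length: float = 0.25,
                  prefix: str = "t") -> PhyloTree:
    """Balanced binary tree (n_leaves a power of two) with uniform branch
    lengths — a convenient deep phylogeny for simulations."""
    if n_leaves < 2 or n_leaves & (n_leaves - 1):
        raise ParameterError("n_leaves must be a power of two >= 2")

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{prefix}{lo + 1}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch_length}"

    newick = build(0, n_leaves)
    # strip the root edge length
    newick = newick.rsplit(":", 1)[0] + ";"
    return PhyloTree.from_newick(newick)


# ---------------------------------------------------------------------------
# end-to-end variant benchmark


@dataclass
class VariantBenchmark:
    """Planted-truth benchmark mirroring the three-group variant contrast:
    surface/variable alloantigen-like variants, buried/conserved
    disease-like mutations, and a mixed neutral group."""

    structures: dict[str, Structure]
    burial_truth: dict[str, dict[ResidueId, str]]
    msa: Msa
    tree: PhyloTree
    true_rates: np.ndarray
    variants: pd.DataFrame
    truth: pd.DataFrame
    numbering: pd.DataFrame
    gene: str = "SYNV"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Materialise all fixture files (PDB/FASTA/Newick/TSV) into a
        directory; returns the path map."""
        from .structure_io import write_pdb

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        struct_dir = out / "structures"
        struct_dir.mkdir(exist_ok=True)
        for sid, st in self.structures.items():
            p = struct_dir / f"{sid}.pdb"
            write_pdb(st, p)
            paths[sid] = p
        paths["msa"] = out / "alignment.fasta"
        self.msa.to_fasta(paths["msa"])
        paths["tree"] = out / "tree.nwk"
        paths["tree"].write_text(self.tree.as_newick() + "\n")
        paths["variants"] = out / "variants.tsv"
        self.variants.to_csv(paths["variants"], sep="\t", index=False)
        paths["truth"] = out / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["numbering"] = out / "numbering_map.tsv"
        self.numbering.to_csv(paths["numbering"], sep="\t", index=False)
        return paths


_FOLD_SIZE = 14          # residues per toy fold
_POSITION_STRIDE = 20    # gene positions reserved per fold


def make_variant_benchmark(
    seed: int = 0,
    group_sizes: tuple[int, int, int] = (17, 13, 8),
    n_leaves: int = 32,
) -> VariantBenchmark:
    """Build the full synthetic study: toy structures, an alignment with
    planted site rates, and a variant table with planted group structure.

    Group design (defaults mirror the published study sizes 17/13/8):
    'hpa'-like variants sit on exposed shell residues whose alignment
    columns evolved fast (rate 3.0); 'disease'-like variants sit on buried
    fold centres with slow columns (rate 0.1); 'neutral' variants mix both
    exposures and both rates half-and-half.
    """
    n_hpa, n_disease, n_neutral = group_sizes
    n_neutral_buried = n_neutral // 2
    n_folds = n_disease + n_neutral_buried
    seq = np.random.SeedSequence([seed, 0xBE7C])
    fold_seeds = np.random.default_rng(seq.spawn(1)[0]).integers(0, 2**31 - 1, n_folds)
    rng = np.random.default_rng(seq.spawn(2)[1])

    structures: dict[str, Structure] = {}
    burial_truth: dict[str, dict[ResidueId, str]] = {}
    numbering_rows = []
    gene = "SYNV"
    exposed_slots: list[tuple[str, int, str]] = []  # (structure_id, position, resname)
    buried_slots: list[tuple[str, int, str]] = []
    for k in range(n_folds):
        first = k * _POSITION_STRIDE + 1
        spec = ToyFoldSpec(
            n_residues=_FOLD_SIZE,
            seed=int(fold_seeds[k]),
            first_number=first,
            structure_id=f"synfold-{k:02d}",
        )
        st, labels = make_toy_fold(spec)
        structures[st.id] = st
        burial_truth[st.id] = labels
        numbering_rows.append(
            {"gene": gene, "structure_id": st.id, "chain": "A",
             "position_offset": 0, "signal_peptide_offset": 0,
             "msa_id": "synmsa", "msa_offset": 0}
        )
        for rid, name, _idx in st.residues():
            slot = (st.id, rid.number, name)
            (buried_slots if labels[rid] == "buried" else exposed_slots).append(slot)

    # assign variants to slots
    rng.shuffle(exposed_slots)
    need_exposed = n_hpa + (n_neutral - n_neutral_buried)
    if len(exposed_slots) < need_exposed or len(buried_slots) < n_folds:
        raise GenerationError("not enough residue slots for the requested sizes")
    hpa_slots = exposed_slots[:n_hpa]
    neutral_exposed = exposed_slots[n_hpa:need_exposed]
    disease_slots = buried_slots[:n_disease]
    neutral_buried = buried_slots[n_disease:n_disease + n_neutral_buried]

    max_pos = n_folds * _POSITION_STRIDE + _FOLD_SIZE
    n_sites = max_pos + 5
    site_rates = np.ones(n_sites)
    rate_truth: dict[int, float] = {}

    def plant(slots, rate):
        for _sid, pos, _name in slots:
            site_rates[pos - 1] = rate
            rate_truth[pos] = rate

    plant(hpa_slots, 3.0)
    plant(disease_slots, 0.1)
    plant(neutral_exposed[: len(neutral_exposed) // 2], 3.0)
    plant(neutral_exposed[len(neutral_exposed) // 2:], 0.1)
    half = len(neutral_buried) // 2
    plant(neutral_buried[:half], 0.1)
    plant(neutral_buried[half:], 3.0)

    tree = balanced_tree(n_leaves)
    msa, true_rates = simulate_alignment(
        SimAlignmentSpec(tree=tree, n_sites=n_sites, site_rates=site_rates,
                         seed=int(rng.integers(0, 2**31 - 1)))
    )

    # variant table with planted groups
    three = {c: ONE_TO_THREE[c] for c in AA_ORDER}
    rows, truth_rows = [], []

    def add_variants(slots, group, tag, exposure):
        for i, (sid, pos, wt3) in enumerate(slots, start=1):
            wt1 = [k for k, v in ONE_TO_THREE.items() if v == wt3][0]
            mut1 = rng.choice([a for a in AA_ORDER if a != wt1])
            vid = f"SYN-{tag}-{i:02d}"
            rows.append(
                {"id": vid, "gene": gene,
                 "substitution": f"{wt3.capitalize()}{pos}{three[mut1].capitalize()}",
                 "group": group, "numbering_scheme": "mature", "domain": "toyfold"}
            )
            truth_rows.append(
                {"id": vid, "structure_id": sid, "position": pos,
                 "true_exposure": exposure, "true_rate": rate_truth[pos]}
            )

    add_variants(hpa_slots, "hpa", "HPA", "exposed")
    add_variants(disease_slots, "disease", "DIS", "buried")
    add_variants(neutral_exposed, "neutral", "NEU", "exposed")
    add_variants(neutral_buried, "neutral", "NEB", "buried")

    return VariantBenchmark(
        structures=structures,
        burial_truth=burial_truth,
        msa=msa,
        tree=tree,
        true_rates=true_rates,
        variants=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        numbering=pd.DataFrame(numbering_rows),
        gene=gene,
    )
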