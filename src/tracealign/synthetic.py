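"""Deterministic synthetic CA traces and perturbed structure families.

The generator emulates the shape of a benchmark family (a shared fold,
members differing by rigid motion, coordinate noise, and a few indels)
with fully known ground-truth residue correspondences, so every pipeline
stage is testable without external structure data. Backbones are
self-avoiding walks with the canonical 3.8 A CA-CA step; members are
perturbed copies of one ancestor. All randomness flows through
numpy's seeded PCG64 generator, so identical seeds give identical
structures on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .structure_io import ONE_TO_THREE, ProteinStructure

__all__ = [
    "FamilyTruth",
    "make_backbone",
    "make_helix",
    "perturb",
    "make_family",
    "random_rotation",
    "truth_recovery",
]

STEP = 3.8  # CA-CA virtual bond, angstrom
MIN_SEPARATION = 3.5  # non-adjacent clash distance, angstrom
BEND_RANGE = (80.0, 150.0)  # allowed CA pseudo-bond angle, degrees

_AA3 = sorted(ONE_TO_THREE.values())


class GenerationError(RuntimeError):
    pass


@dataclass
class FamilyTruth:
    """A synthetic family with its ground truth.

    ``truth_mappings[k]`` maps each surviving residue of member k to its
    ancestor residue index: a list of (member_index, ancestor_index) pairs,
    monotone in both coordinates.
    """

    ancestor: ProteinStructure
    members: list[ProteinStructure]
    truth_mappings: list[list[tuple[int, int]]]
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params,
                "members": [m.id for m in self.members],
                "truth_mappings": self.truth_mappings,
            },
            indent=2,
        )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized random quaternion."""
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


def _random_names(L: int, rng: np.random.Generator) -> list[str]:
    return [_AA3[k] for k in rng.integers(0, len(_AA3), size=L)]


def make_backbone(L: int, seed: int, id: str = "synthetic") -> ProteinStructure:
    """Self-avoiding CA walk: step exactly 3.8 A, bend angles in
    [80, 150] degrees, no non-adjacent pair closer than 3.5 A.

    Steps violating the clash constraint are resampled (up to 200 tries per
    step); if a chain dead-ends, the whole walk restarts (up to 100 times)
    before giving up.
    """
    if L < 5:
        raise GenerationError("backbone length must be >= 5")
    rng = np.random.default_rng(seed)
    for _restart in range(100):
        coords = np.zeros((L, 3))
        coords[1] = coords[0] + STEP * _random_unit(rng)
        ok = True
        for k in range(2, L):
            placed = False
            prev_dir = coords[k - 1] - coords[k - 2]
            prev_dir /= np.linalg.norm(prev_dir)
            for _try in range(200):
                bend = np.deg2rad(rng.uniform(*BEND_RANGE))
                # random direction at the sampled bend angle from prev_dir
                perp = np.cross(prev_dir, _random_unit(rng))
                norm = np.linalg.norm(perp)
                if norm < 1e-9:
                    continue
                perp /= norm
                direction = np.cos(np.pi - bend) * prev_dir + np.sin(np.pi - bend) * perp
                candidate = coords[k - 1] + STEP * direction
                if k >= 2:
                    dist = np.linalg.norm(coords[: k - 1] - candidate, axis=1)
                    if (dist < MIN_SEPARATION).any():
                        continue
                coords[k] = candidate
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return ProteinStructure(
                id=id,
                residue_names=_random_names(L, rng),
                residue_numbers=list(range(1, L + 1)),
                coords=coords,
            )
    raise GenerationError(f"backbone placement failed for L={L}, seed={seed}")


def make_helix(L: int, id: str = "helix") -> ProteinStructure:
    """Ideal alpha-helix CA trace: radius 2.3 A, rise 1.5 A per residue,
    100 degrees of turn per residue. Deterministic (no randomness)."""
    if L < 3:
        raise GenerationError("helix length must be >= 3")
    k = np.arange(L)
    theta = np.deg2rad(100.0) * k
    coords = np.stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k], axis=1
    )
    names = ["ALA"] * L
    return ProteinStructure(
        id=id, residue_names=names, residue_numbers=list(range(1, L + 1)), coords=coords
    )


def perturb(
    s: ProteinStructure,
    noise_sigma: float,
    n_indels: int,
    seed: int,
    id: str | None = None,
) -> tuple[ProteinStructure, list[tuple[int, int]]]:
    """Rigid motion + isotropic Gaussian noise + random single-residue indels.

    Insertions are placed at the geometric midpoint of their neighbors (a
    slight clash with the 3.8 A step, by design — inserted residues have no
    ancestor). The returned truth mapping links each surviving residue of
    the perturbed copy to its ancestor index and is monotone.
    """
    rng = np.random.default_rng(seed)
    R = random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    coords = s.coords @ R.T + t
    if noise_sigma > 0:
        coords = coords + rng.normal(scale=noise_sigma, size=coords.shape)

    names = list(s.residue_names)
    ancestors: list[int | None] = list(range(len(s)))
    coords_list = [c for c in coords]

    for _ in range(n_indels):
        if len(coords_list) <= 5:
            raise GenerationError("resulting structure would be shorter than 5 residues")
        if rng.random() < 0.5:  # deletion
            pos = int(rng.integers(0, len(coords_list)))
            del coords_list[pos], names[pos], ancestors[pos]
        else:  # insertion between pos and pos+1
            pos = int(rng.integers(0, len(coords_list) - 1))
            mid = 0.5 * (coords_list[pos] + coords_list[pos + 1])
            coords_list.insert(pos + 1, mid)
            names.insert(pos + 1, _AA3[int(rng.integers(0, len(_AA3)))])
            ancestors.insert(pos + 1, None)

    if len(coords_list) < 5:
        raise GenerationError("resulting structure shorter than 5 residues")
    out = ProteinStructure(
        id=id or f"{s.id}_perturbed",
        residue_names=names,
        residue_numbers=list(range(1, len(names) + 1)),
        coords=np.array(coords_list),
    )
    mapping = [(k, a) for k, a in enumerate(ancestors) if a is not None]
    return out, mapping


def make_family(
    n: int,
    L: int,
    noise_sigma: float,
    n_indels: int,
    seed: int,
) -> FamilyTruth:
    """One ancestor backbone plus ``n`` independently perturbed members.

    Member sub-seeds derive deterministically from ``seed`` via the seeded
    generator, so the whole family is a pure function of its parameters.
    """
    if n < 2:
        raise GenerationError("family needs at least 2 members")
    ancestor = make_backbone(L, seed, id="ancestor")
    rng = np.random.default_rng(seed + 1)
    subseeds = rng.integers(0, 2**31 - 1, size=n)
    members = []
    mappings = []
    for k in range(n):
        member, mapping = perturb(
            ancestor, noise_sigma, n_indels, int(subseeds[k]), id=f"member{k:02d}"
        )
        members.append(member)
        mappings.append(mapping)
    return FamilyTruth(
        ancestor=ancestor,
        members=members,
        truth_mappings=mappings,
        params={
            "n": n,
            "L": L,
            "noise_sigma": noise_sigma,
            "n_indels": n_indels,
            "seed": seed,
        },
    )


def truth_recovery(msta, family: FamilyTruth) -> float:
    """Fraction of ancestor residues whose correspondence the alignment
    recovers: a core column counts when every member's residue in that
    column maps back to the same ancestor index. Divided by the ancestor
    length, so missed and wrong columns both lose credit."""
    from .msta import GAP

    to_ancestor = []
    order = {sid: r for r, sid in enumerate(msta.structure_ids)}
    for member, mapping in zip(family.members, family.truth_mappings):
        lut = {k: a for k, a in mapping}
        to_ancestor.append((order[member.id], lut))

    recovered = 0
    for c in range(msta.n_columns):
        col = msta.rows[:, c]
        if (col == GAP).any():
            continue
        ancestors = set()
        ok = True
        for row, lut in to_ancestor:
            a = lut.get(int(col[row]))
            if a is None:
                ok = False
                break
            ancestors.add(a)
        if ok and len(ancestors) == 1:
            recovered += 1
    return recovered / len(family.ancestor)
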