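"""The Operational Module Unit (OMU) system.

Differential modules from different drugs that share edges describe the same
drug-altered regulatory program.  An OMU collects such a recurring program:

* ``structure`` -- the TF->gene edges shared by its member modules,
* ``members`` -- the (sample, module index) pairs that contributed,
* ``mean_grmax`` -- the members' sample GRmax values, each weighted by the
  fraction of its sample's total differential-modularity mass that the member
  module carries.

The system is built by a single greedy pass over all cross-sample module
pairs in descending Jaccard similarity (processing the most similar pairs
first makes early OMUs maximally specific).  Each drug is then summarized as
a sparse non-negative activity vector over the OMU system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diffmod import DifferentialModule, Edge
from .io_formats import GRTable

logger = logging.getLogger("omu_synergy")

Member = tuple[str, int]  # (sample id, module index)


@dataclass
class OMU:
    omu_id: int
    structure: frozenset[Edge]
    members: list[Member]
    mean_grmax: float = float("nan")

    def __post_init__(self) -> None:
        if not self.structure:
            raise ValueError("OMU structure must be non-empty")
        if not self.members:
            raise ValueError("OMU must have at least one member")


@dataclass
class OMUSystem:
    omus: list[OMU]
    min_similarity: float

    def __len__(self) -> int:
        return len(self.omus)

    def __iter__(self):
        return iter(self.omus)

    def member_index(self) -> dict[Member, list[int]]:
        """Member (sample, module) -> positions of the OMUs it belongs to."""
        out: dict[Member, list[int]] = {}
        for pos, omu in enumerate(self.omus):
            for member in omu.members:
                out.setdefault(member, []).append(pos)
        return out

    def to_dict(self) -> dict:
        return {
            "min_similarity": self.min_similarity,
            "omus": [
                {
                    "id": o.omu_id,
                    "structure": sorted([t, g] for t, g in o.structure),
                    "members": [[s, i] for s, i in o.members],
                    "mean_grmax": o.mean_grmax,
                }
                for o in self.omus
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OMUSystem":
        omus = [
            OMU(
                omu_id=int(o["id"]),
                structure=frozenset((t, g) for t, g in o["structure"]),
                members=[(s, int(i)) for s, i in o["members"]],
                mean_grmax=float(o["mean_grmax"]),
            )
            for o in d["omus"]
        ]
        return cls(omus=omus, min_similarity=float(d["min_similarity"]))


@dataclass
class OMUVector:
    """A drug's sparse activity profile over the OMU system."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("OMU vector components must be non-negative")
        if not (self.values > 0).any():
            raise ValueError(f"OMU vector for {self.sample_id!r} is all zero")


def module_jaccard(a: DifferentialModule, b: DifferentialModule) -> float:
    """Jaccard index |A & B| / (|A| + |B| - |A & B|) over the edge sets."""
    ea, eb = a.edge_set, b.edge_set
    if not ea or not eb:
        raise ValueError("modules must be non-empty")
    inter = len(ea & eb)
    return inter / (len(ea) + len(eb) - inter)


def _jaccard_sets(x: frozenset, y: frozenset) -> float:
    inter = len(x & y)
    if inter == 0:
        return 0.0
    return inter / (len(x) + len(y) - inter)


def build_omu_system(
    modules: list[DifferentialModule], min_similarity: float = 0.25
) -> OMUSystem:
    """Greedy construction of the OMU compendium.

    Cross-sample module pairs are visited in descending Jaccard order (ties
    broken by lexicographic (sample, index) pair id).  A qualifying pair
    (J >= min_similarity) contributes its shared edge set: if that set has at
    least one edge in common with an existing OMU's structure, the pair's
    modules join that OMU and the structure narrows to the intersection of
    structure and shared set (kept unchanged if the intersection would be
    empty, which cannot happen for the first extension); otherwise the
    shared set founds a new OMU.  Processing the most similar pairs first
    means each OMU's structure converges onto the edge core shared by its
    whole member set.  Modules left without any qualifying partner become
    singleton OMUs from their full edge set, so every module is a member of
    at least one OMU.  A module may belong to several OMUs.
    """
    if not modules:
        raise ValueError("no modules: cannot build an OMU system")
    keyed = sorted(modules, key=lambda m: (m.sample_id, m.index))
    pairs = []
    for i in range(len(keyed)):
        for j in range(i + 1, len(keyed)):
            a, b = keyed[i], keyed[j]
            if a.sample_id == b.sample_id:
                continue
            jac = module_jaccard(a, b)
            if jac >= min_similarity:
                pairs.append((jac, a, b))
    # descending similarity; ties by lexicographic pair id
    pairs.sort(key=lambda p: (-p[0], p[1].sample_id, p[1].index,
                              p[2].sample_id, p[2].index))

    omus: list[OMU] = []
    placed: set[Member] = set()
    for jac, a, b in pairs:
        shared = a.edge_set & b.edge_set
        target = None
        for omu in omus:
            if omu.structure & shared:
                target = omu
                break
        members = [(a.sample_id, a.index), (b.sample_id, b.index)]
        if target is None:
            omus.append(OMU(omu_id=len(omus), structure=frozenset(shared),
                            members=list(members)))
        else:
            target.structure = frozenset(target.structure & shared)
            for member in members:
                if member not in target.members:
                    target.members.append(member)
        placed.update(members)
    for mod in keyed:
        member = (mod.sample_id, mod.index)
        if member not in placed:
            omus.append(OMU(omu_id=len(omus), structure=mod.edge_set,
                            members=[member]))
    logger.info("build_omu_system: %d modules -> %d OMUs", len(modules), len(omus))
    return OMUSystem(omus=omus, min_similarity=min_similarity)


def assign_mean_grmax(
    system: OMUSystem, gr: GRTable, modules: list[DifferentialModule]
) -> OMUSystem:
    """Attach each OMU's mean GRmax (in place; the system is also returned).

    mean GRmax = sum over members of GR(sample) * X_member divided by the sum
    over *distinct* member samples of that sample's total module weight, where
    X is the member module's weight.  Each member therefore contributes its
    sample's GRmax in proportion to the share of the sample's differential
    signal it carries, which keeps the mean inside [-1, 1].
    """
    by_member: dict[Member, DifferentialModule] = {
        (m.sample_id, m.index): m for m in modules
    }
    sample_total: dict[str, float] = {}
    for m in modules:
        sample_total[m.sample_id] = sample_total.get(m.sample_id, 0.0) + m.module_weight
    for omu in system:
        num = 0.0
        denom_samples: set[str] = set()
        for sample_id, index in omu.members:
            if sample_id not in gr:
                raise KeyError(f"no GRmax entry for sample {sample_id!r}")
            member = by_member.get((sample_id, index))
            if member is None:
                raise KeyError(f"member module {(sample_id, index)} not in inventory")
            num += gr[sample_id] * member.module_weight
            denom_samples.add(sample_id)
        denom = sum(sample_total[s] for s in denom_samples)
        omu.mean_grmax = num / denom if denom > 0 else 0.0
        if not -1.0 <= omu.mean_grmax <= 1.0:
            raise AssertionError("mean GRmax escaped [-1, 1]")
    return system


def omu_vector(
    sample_modules: list[DifferentialModule], system: OMUSystem
) -> OMUVector:
    """Sparse activity vector of one drug over the OMU system.

    Component k sums the full module weight of each of the sample's modules
    that is a member of OMU k (zero where the sample has no member module).
    """
    if not sample_modules:
        raise ValueError("sample has no differential modules; no vector representable")
    sample_ids = {m.sample_id for m in sample_modules}
    if len(sample_ids) != 1:
        raise ValueError("modules from multiple samples passed to omu_vector")
    (sample_id,) = sample_ids
    index = system.member_index()
    values = np.zeros(len(system))
    for mod in sample_modules:
        for pos in index.get((sample_id, mod.index), []):
            values[pos] += mod.module_weight
    return OMUVector(sample_id=sample_id, values=values)
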