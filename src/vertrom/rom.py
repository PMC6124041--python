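"""Contact detection and the collision-terminated range-of-motion search.

A joint's maximal displacement in a mobility profile is the largest rotation
from neutral with no bone-on-bone contact: the posterior vertebra is rotated
about the joint pivot until the minimum inter-surface distance over the
allowed part pairs drops to the contact tolerance.  A coarse pre-sweep finds
the first-contact bracket (guarding against contact that appears and
disappears); bisection then refines the angle to ``tol_deg``.  These maxima
are osteological: no soft tissue is modelled, so they bracket, not predict,
in-vivo motion.

Two trial modes are provided.  PCVM (paired cervical vertebral mobility)
keeps the preserved intervertebral spacing and lets any part pair terminate
the search.  MISM (minimum intervertebral space mobility) first collapses
each gap until the centra touch; centrum-centrum contact then cannot define
the stop and is excluded from the rule, though its interpenetration is still
measured and reported against a cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from ._proximity import PartSurface, pair_min_distance, penetration_depth, sphere_gap
from .articulation import ColumnPose, apply_rotation, neutral_pose, reduce_spacing
from .errors import ContactRuleError, ParameterError
from .mesh_io import LabeledVertebraMesh

__all__ = [
    "ContactRule",
    "ContactReport",
    "ROMTable",
    "check_contact",
    "max_displacement",
    "run_trial",
    "measure_line_angle",
]

TRIAL_PROFILES = ("lateral", "dorsal", "ventral")


def _norm_pair(pa: str, pb: str) -> tuple[str, str]:
    return (pa, pb) if pa <= pb else (pb, pa)


@dataclass(frozen=True)
class ContactRule:
    """Which part pairs terminate the search, and at what tolerance.

    ``included`` is either the wildcard ``"*"`` or a set of unordered part-name
    pairs; ``excluded`` pairs never terminate the search regardless.
    ``epsilon`` (mm) is the surface distance at or below which two parts are
    in contact; ``penetration_cap`` (mm) is the depth beyond which measured
    interpenetration of an excluded pair is flagged in the results.
    """

    included: str | frozenset[tuple[str, str]] = "*"
    excluded: frozenset[tuple[str, str]] = frozenset()
    epsilon: float = 0.1
    penetration_cap: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ParameterError("contact tolerance epsilon must be > 0")
        if self.included != "*":
            object.__setattr__(
                self, "included", frozenset(_norm_pair(*p) for p in self.included)
            )
        object.__setattr__(
            self, "excluded", frozenset(_norm_pair(*p) for p in self.excluded)
        )

    def allows(self, pa: str, pb: str) -> bool:
        pair = _norm_pair(pa, pb)
        if pair in self.excluded:
            return False
        return self.included == "*" or pair in self.included

    def excluding(self, *pairs: tuple[str, str]) -> "ContactRule":
        extra = frozenset(_norm_pair(*p) for p in pairs)
        return dc_replace(self, excluded=self.excluded | extra)

    def candidate_pairs(
        self, parts_a: set[str], parts_b: set[str]
    ) -> list[tuple[str, str]]:
        return sorted(
            {(pa, pb) for pa in sorted(parts_a) for pb in sorted(parts_b) if self.allows(pa, pb)}
        )

    def to_dict(self) -> dict:
        return {
            "included": "*" if self.included == "*" else sorted(map(list, self.included)),
            "excluded": sorted(map(list, self.excluded)),
            "epsilon_mm": self.epsilon,
            "penetration_cap_mm": self.penetration_cap,
        }


@dataclass
class ContactReport:
    """Result of a contact query between two posed vertebrae."""

    in_contact: bool
    min_distance: float
    part_pair: tuple[str, str] | None
    witness_a: np.ndarray | None
    witness_b: np.ndarray | None
    epsilon: float


class _SurfaceCache:
    """Per-part PartSurface cache keyed by (vertebra id, part name)."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], PartSurface] = {}

    def get(self, vert: LabeledVertebraMesh, part: str) -> PartSurface:
        key = (vert.id, part)
        if key not in self._store:
            mesh = vert.parts[part]
            self._store[key] = PartSurface(mesh.vertices, mesh.faces)
        return self._store[key]


def check_contact(
    vA: LabeledVertebraMesh,
    vB: LabeledVertebraMesh,
    pose: ColumnPose,
    rule: ContactRule,
    cache: _SurfaceCache | None = None,
) -> ContactReport:
    """Minimum inter-surface distance between two posed vertebrae.

    Only part pairs the rule allows are queried.  Pairs whose bounding-sphere
    separation cannot beat the current best distance are skipped, so the
    query cost is dominated by the few nearly-touching pairs.
    """
    idx = {id(v): i for i, v in enumerate(pose.column)}
    try:
        ia, ib = idx[id(vA)], idx[id(vB)]
    except KeyError as exc:
        raise ParameterError("vertebra is not part of the pose") from exc
    ta, tb = pose.transforms[ia], pose.transforms[ib]
    cache = cache or _SurfaceCache()

    pairs = rule.candidate_pairs(vA.part_names, vB.part_names)
    if not pairs:
        raise ContactRuleError(
            f"contact rule excludes every part pair between {vA.id} and {vB.id}"
        )

    bounded = []
    for pa, pb in pairs:
        sa, sb = cache.get(vA, pa), cache.get(vB, pb)
        bounded.append((sphere_gap(sa, ta, sb, tb), pa, pb, sa, sb))
    bounded.sort(key=lambda item: item[0])

    best = np.inf
    best_pair = None
    best_wa = best_wb = None
    for lower, pa, pb, sa, sb in bounded:
        if lower >= best:
            break
        d, wa, wb = pair_min_distance(sa, ta, sb, tb)
        if d < best:
            best, best_pair, best_wa, best_wb = d, (pa, pb), wa, wb
    return ContactReport(
        in_contact=bool(best <= rule.epsilon),
        min_distance=float(best),
        part_pair=best_pair,
        witness_a=best_wa,
        witness_b=best_wb,
        epsilon=rule.epsilon,
    )


def max_displacement(
    pose: ColumnPose,
    joint: int,
    profile: str,
    rule: ContactRule,
    tol_deg: float = 0.01,
    bracket: float = 90.0,
    presweep: float = 1.0,
    cache: _SurfaceCache | None = None,
) -> tuple[float, ContactReport | None]:
    """Largest contact-free rotation of a joint in one mobility profile.

    Returns ``(angle_deg, first_contact_report)``.  The angle is the largest
    rotation in ``[0, bracket]`` with no allowed-pair contact, bisected to
    within ``tol_deg``; the report describes the contact just beyond it.  If
    the pair is already in contact at neutral the angle is 0; if no contact
    occurs up to ``bracket`` the report is ``None`` (search-bracket limit).
    """
    if tol_deg <= 0:
        raise ParameterError("tol_deg must be > 0")
    vA, vB = pose.column[joint], pose.column[joint + 1]
    cache = cache or _SurfaceCache()

    def probe(phi: float) -> ContactReport:
        p = apply_rotation(pose, joint, profile, phi) if phi else pose
        return check_contact(vA, vB, p, rule, cache)

    report = probe(0.0)
    if report.in_contact:
        return 0.0, report

    # coarse sweep: take the FIRST contact bracket so non-monotone contact
    # (contact that appears then disappears) is not skipped over
    lo, hi = 0.0, None
    first = None
    phi = presweep
    while phi <= bracket + 1e-12:
        r = probe(phi)
        if r.in_contact:
            hi, first = phi, r
            break
        lo = phi
        phi += presweep
    if hi is None:
        if lo < bracket:  # bracket not a multiple of presweep
            r = probe(bracket)
            if r.in_contact:
                hi, first = bracket, r
            else:
                return bracket, None
        else:
            return bracket, None

    while hi - lo > tol_deg:
        mid = (lo + hi) / 2
        r = probe(mid)
        if r.in_contact:
            hi, first = mid, r
        else:
            lo = mid
    return lo, first


@dataclass
class ROMTable:
    """Per-joint maximal angles for the three mobility profiles in one trial."""

    trial: str
    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        joint: str,
        profile: str,
        angle_deg: float | None,
        stop_pair: tuple[str, str] | None,
        limited: bool = False,
        damaged: bool = False,
        missing: bool = False,
        excluded_penetration_mm: float = 0.0,
    ) -> None:
        if angle_deg is not None and angle_deg < 0:
            raise ParameterError("ROM angles are non-negative")
        self.rows.append(
            {
                "joint": joint,
                "profile": profile,
                "trial": self.trial,
                "angle_deg": np.nan if angle_deg is None else float(angle_deg),
                "stop_part_a": None if stop_pair is None else stop_pair[0],
                "stop_part_b": None if stop_pair is None else stop_pair[1],
                "bracket_limited": bool(limited),
                "damaged": bool(damaged),
                "missing": bool(missing),
                "excluded_penetration_mm": float(excluded_penetration_mm),
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "joint",
            "profile",
            "trial",
            "angle_deg",
            "stop_part_a",
            "stop_part_b",
            "bracket_limited",
            "damaged",
            "missing",
            "excluded_penetration_mm",
        ]
        return pd.DataFrame(self.rows, columns=cols)

    def to_angle_table(self, drop_missing: bool = True) -> pd.DataFrame:
        df = self.to_dataframe()
        if drop_missing:
            df = df[~df["missing"]]
        return df[["joint", "profile", "trial", "angle_deg"]].reset_index(drop=True)


def run_trial(
    column: list[LabeledVertebraMesh],
    gaps: list[float] | None,
    mode: str,
    rule: ContactRule | None = None,
    tol_deg: float = 0.01,
    bracket: float = 90.0,
    presweep: float = 1.0,
    damaged_ids: set[str] | None = None,
    reduce_eps: float = 1e-3,
) -> ROMTable:
    """Run a full PCVM or MISM trial over every consecutive vertebra pair.

    Vertebrae are manipulated two at a time (the anterior one fixed), each
    pair posed independently in its neutral spacing.  ``mode`` selects the
    spacing regime: ``"PCVM"`` preserves the given gaps and lets every part
    pair stop the search; ``"MISM"`` collapses each gap to centrum contact
    first and excludes centrum-centrum contact from the stopping rule.

    Joints with damage-masked vertebrae are computed but flagged; joints
    where the rule leaves no part pair to test are marked missing.
    """
    if mode not in ("PCVM", "MISM"):
        raise ParameterError("mode must be 'PCVM' or 'MISM'")
    if len(column) < 2:
        raise ParameterError("need at least two vertebrae")
    rule = rule or ContactRule()
    damaged_ids = damaged_ids or set()
    if gaps is None:
        gaps = [None] * (len(column) - 1)  # type: ignore[list-item]

    table = ROMTable(trial=mode)
    cache = _SurfaceCache()
    for j in range(len(column) - 1):
        vA, vB = column[j], column[j + 1]
        joint_id = f"{vA.id}-{vB.id}"
        gap_j = None if gaps[j] is None else [float(gaps[j])]
        pose = neutral_pose([vA, vB], gaps=gap_j)
        trial_rule = rule
        if mode == "MISM":
            pose = reduce_spacing(pose, eps=reduce_eps)
            trial_rule = rule.excluding(("centrum", "centrum"))
        damaged = vA.id in damaged_ids or vB.id in damaged_ids

        for profile in TRIAL_PROFILES:
            try:
                angle, report = max_displacement(
                    pose, 0, profile, trial_rule,
                    tol_deg=tol_deg, bracket=bracket, presweep=presweep, cache=cache,
                )
            except ContactRuleError:
                table.add(joint_id, profile, None, None, damaged=damaged, missing=True)
                continue
            pen = 0.0
            if mode == "MISM" and angle > 0:
                final = apply_rotation(pose, 0, profile, angle)
                pen = penetration_depth(
                    cache.get(vA, "centrum"), final.transforms[0],
                    cache.get(vB, "centrum"), final.transforms[1],
                )
            table.add(
                joint_id,
                profile,
                angle,
                None if report is None else report.part_pair,
                limited=report is None,
                damaged=damaged,
                excluded_penetration_mm=pen,
            )
    return table


def measure_line_angle(
    pose: ColumnPose,
    joint: int,
    profile: str,
    replicates: int = 3,
    jitter_sd_deg: float = 0.0,
    seed: int = 0,
) -> float:
    """Measure a joint angle the way it is done on screen captures.

    A straight line is fitted along each vertebra's centrum axis -- in the
    median plane for the dorsal/ventral profiles, in the frontal plane
    (dorsal view) for the lateral profile -- and the acute angle between the
    two intersecting lines is returned.  ``replicates`` measurements are
    averaged, each perturbed by zero-mean Gaussian jitter of
    ``jitter_sd_deg`` emulating manual triplicate measurement; with zero
    jitter the value is deterministic and equals the commanded joint angle.
    """
    if not 0 <= joint < len(pose.column) - 1:
        raise ParameterError(f"joint index {joint} out of range")
    if profile not in ("lateral", "lateral_left", "dorsal", "ventral"):
        raise ParameterError(f"unknown profile {profile!r}")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")

    dirs = []
    for i in (joint, joint + 1):
        rot = pose.transforms[i][:3, :3]
        frame = np.asarray(pose.column[i].frame, dtype=float)
        dirs.append(rot @ frame[0])
    u, v = dirs
    if profile in ("dorsal", "ventral"):
        u, v = u[[0, 2]], v[[0, 2]]  # median plane (x, z)
    else:
        u, v = u[[0, 1]], v[[0, 1]]  # frontal plane (x, y)
    cosang = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    true_angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    if jitter_sd_deg == 0.0:
        return true_angle
    rng = np.random.default_rng(seed)
    return float(np.mean(true_angle + rng.normal(0.0, jitter_sd_deg, size=replicates)))
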