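"""Object catalog, constrained table arrangements, and the shifted-scene design.

The reaching task places six everyday objects -- three natural (apple,
banana, pear) and three man-made (pencil case, puncher, stapler) -- on an
80 x 80 cm table top. Each of the six objects serves as the reach target in
four randomly generated arrangements (24 arrangements). Every arrangement is
then presented five times: once unchanged (baseline) and four times with two
landmark objects shifted horizontally (left/right x semantically
congruent/incongruent), for 120 distinct scenes.

Coordinate convention: origin at the table centre, x positive to the
participant's right, y positive away from the participant, all lengths in cm.
Object footprints are axis-aligned length x width rectangles; overlap tests
inflate each footprint by half the padding so that any two placed objects
keep at least ``padding_cm`` of clearance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

NATURAL = "natural"
MAN_MADE = "man-made"
CLUSTERS = (NATURAL, MAN_MADE)

#: Half-extent of the table top (cm); the top is 80 x 80 cm.
TABLE_HALF_CM = 40.0


@dataclass(frozen=True)
class ObjectSpec:
    """One object of the scene catalog.

    ``length_cm`` extends along x (the shift axis), ``width_cm`` along y.
    ``height_cm`` is carried as metadata only; collision tests are planar.
    """

    object_id: str
    cluster: str
    length_cm: float
    width_cm: float
    height_cm: float

    def __post_init__(self) -> None:
        if min(self.length_cm, self.width_cm, self.height_cm) <= 0:
            raise ValueError("object dimensions must be positive")
        if self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r}")

    @property
    def half_x(self) -> float:
        return self.length_cm / 2.0

    @property
    def half_y(self) -> float:
        return self.width_cm / 2.0


_CATALOG_ROWS = [
    ("apple", NATURAL, 8.0, 7.0, 8.0),
    ("banana", NATURAL, 3.0, 15.0, 6.0),
    ("pear", NATURAL, 8.0, 8.0, 12.0),
    ("pencil case", MAN_MADE, 7.0, 8.0, 13.0),
    ("puncher", MAN_MADE, 8.0, 12.0, 6.0),
    ("stapler", MAN_MADE, 3.0, 12.0, 8.0),
]


def generate_catalog() -> list[ObjectSpec]:
    """Return the six-object catalog (three natural, three man-made)."""
    return [ObjectSpec(*row) for row in _CATALOG_ROWS]


@dataclass(frozen=True)
class LayoutConstraints:
    """Geometric constraints for arrangement generation.

    ``placement_half_cm`` restricts object centres to a central square zone;
    the default 25 cm zone yields realized target-cluster distances around
    25 cm on the 80 cm table. ``balance_tol_cm`` bounds the absolute
    difference between the dataset means of the own- and other-cluster
    target distances.
    """

    table_half_cm: float = TABLE_HALF_CM
    placement_half_cm: float = 25.0
    fixation_radius_cm: float = 10.0
    padding_cm: float = 1.0
    balance_tol_cm: float = 3.0
    shift_low_cm: float = 4.0
    shift_high_cm: float = 6.0
    max_position_tries: int = 200
    max_arrangement_tries: int = 200
    max_set_tries: int = 200
    max_shift_tries: int = 100


@dataclass(frozen=True)
class SceneArrangement:
    """One table layout: six object placements and a designated target."""

    arrangement_id: int
    target_id: str
    positions: dict[str, tuple[float, float]]
    clusters: dict[str, str]
    fixation_zone_radius_cm: float = 10.0

    @property
    def target_position(self) -> tuple[float, float]:
        return self.positions[self.target_id]

    @property
    def target_cluster(self) -> str:
        return self.clusters[self.target_id]

    def members(self, cluster: str, exclude_target: bool = False) -> list[str]:
        out = [o for o, c in self.clusters.items() if c == cluster]
        if exclude_target and self.target_id in out:
            out.remove(self.target_id)
        return out


@dataclass(frozen=True)
class TrialCondition:
    """One scene of the design: an arrangement plus an (optional) shift."""

    condition_id: int
    arrangement_id: int
    shift_direction: str  # "none" | "left" | "right"
    congruence: str  # "baseline" | "congruent" | "incongruent"
    shifted_ids: tuple[str, ...] = ()
    displacements_cm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        is_base = self.congruence == "baseline"
        if is_base != (self.shift_direction == "none") or is_base != (len(self.shifted_ids) == 0):
            raise ValueError("baseline iff no shift direction iff no shifted objects")
        if not is_base:
            if len(self.shifted_ids) != 2:
                raise ValueError("shift conditions displace exactly two objects")
            sign = -1.0 if self.shift_direction == "left" else 1.0
            if any(np.sign(self.displacements_cm[o]) != sign for o in self.shifted_ids):
                raise ValueError("displacement signs must match the shift direction")


@dataclass(frozen=True)
class ClusterDistances:
    """Mean planar distance from the target to its own / the other cluster."""

    delta_T_own_C_cm: float
    delta_T_other_C_cm: float

    @property
    def advantage_cm(self) -> float:
        """Spatial advantage of congruence: dTotherC - dTownC."""
        return self.delta_T_other_C_cm - self.delta_T_own_C_cm


# ---------------------------------------------------------------------------
# planar geometry helpers

def _rect(obj: ObjectSpec, pos: tuple[float, float], inflate: float = 0.0):
    x, y = pos
    return (x - obj.half_x - inflate, x + obj.half_x + inflate,
            y - obj.half_y - inflate, y + obj.half_y + inflate)


def _rects_overlap(a, b) -> bool:
    return not (a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2])


def _rect_intersects_disc(rect, radius: float, cx: float = 0.0, cy: float = 0.0) -> bool:
    dx = max(rect[0] - cx, 0.0, cx - rect[1])
    dy = max(rect[2] - cy, 0.0, cy - rect[3])
    return dx * dx + dy * dy < radius * radius


def _placement_ok(obj, pos, placed, constraints: LayoutConstraints) -> bool:
    """placed: list of (ObjectSpec, pos) already on the table."""
    rect = _rect(obj, pos)
    if (rect[0] < -constraints.table_half_cm or rect[1] > constraints.table_half_cm
            or rect[2] < -constraints.table_half_cm or rect[3] > constraints.table_half_cm):
        return False
    if _rect_intersects_disc(rect, constraints.fixation_radius_cm):
        return False
    half_pad = constraints.padding_cm / 2.0
    mine = _rect(obj, pos, half_pad)
    for other, opos in placed:
        if _rects_overlap(mine, _rect(other, opos, half_pad)):
            return False
    return True


def _shifts_feasible(arrangement: SceneArrangement, catalog_by_id, constraints) -> bool:
    """Conservative check that every candidate landmark shift stays valid.

    An arrangement is accepted only if, for both directions, the congruent
    pair and all three incongruent pair options can be displaced by *any*
    magnitude in [shift_low, shift_high] without leaving the table or
    touching a stationary object. Stationary clearance uses the swept
    footprint over the whole magnitude range; the two co-shifted objects,
    which move nearly together, are checked with their maximal relative
    displacement instead.
    """
    half_pad = constraints.padding_cm / 2.0
    lo, hi = constraints.shift_low_cm, constraints.shift_high_cm
    rel = (hi - lo) / 2.0
    target = arrangement.target_id
    own = tuple(arrangement.members(arrangement.target_cluster, exclude_target=True))
    other_cluster = NATURAL if arrangement.target_cluster == MAN_MADE else MAN_MADE
    other = arrangement.members(other_cluster)
    pair_options = [own] + list(itertools.combinations(sorted(other), 2))
    for sign in (-1.0, 1.0):
        for pair in pair_options:
            for oid in pair:
                obj = catalog_by_id[oid]
                pos = arrangement.positions[oid]
                swept = list(_rect(obj, pos, half_pad))
                if sign > 0:
                    swept[0] += lo
                    swept[1] += hi
                else:
                    swept[0] -= hi
                    swept[1] -= lo
                if (swept[0] + half_pad < -constraints.table_half_cm
                        or swept[1] - half_pad > constraints.table_half_cm):
                    return False
                partner_rect = _rect(obj, pos, half_pad + rel)
                for other_id, opos in arrangement.positions.items():
                    if other_id == oid or other_id == target:
                        continue
                    if other_id in pair:
                        if _rects_overlap(partner_rect,
                                          _rect(catalog_by_id[other_id], opos, half_pad + rel)):
                            return False
                    elif _rects_overlap(tuple(swept),
                                        _rect(catalog_by_id[other_id], opos, half_pad)):
                        return False
    return True


def _sample_arrangement(catalog, target_id, arrangement_id, constraints, rng) -> SceneArrangement | None:
    for _ in range(constraints.max_arrangement_tries):
        placed: list[tuple[ObjectSpec, tuple[float, float]]] = []
        ok = True
        for obj in catalog:
            lo_x = -(constraints.placement_half_cm)
            for _ in range(constraints.max_position_tries):
                pos = (rng.uniform(lo_x, -lo_x), rng.uniform(lo_x, -lo_x))
                if _placement_ok(obj, pos, placed, constraints):
                    placed.append((obj, pos))
                    break
            else:
                ok = False
                break
        if ok:
            arr = SceneArrangement(
                arrangement_id=arrangement_id,
                target_id=target_id,
                positions={o.object_id: p for o, p in placed},
                clusters={o.object_id: o.cluster for o in catalog},
                fixation_zone_radius_cm=constraints.fixation_radius_cm,
            )
            if _shifts_feasible(arr, {o.object_id: o for o in catalog}, constraints):
                return arr
    return None


def generate_arrangements(
    catalog: list[ObjectSpec] | None = None,
    n_per_target: int = 4,
    constraints: LayoutConstraints | None = None,
    seed: int = 0,
) -> list[SceneArrangement]:
    """Generate ``6 * n_per_target`` constrained arrangements.

    Rejection-samples object positions until no footprint overlaps another,
    intersects the central fixation zone, or leaves the table, then
    regenerates the whole set until the dataset-level means of dTownC and
    dTotherC agree within ``balance_tol_cm``. Deterministic for a fixed seed.
    """
    catalog = list(catalog) if catalog is not None else generate_catalog()
    if sorted(c for c in (o.cluster for o in catalog)).count(NATURAL) != 3 or len(catalog) != 6:
        raise ValueError("catalog must contain six objects, three per cluster")
    if n_per_target < 1:
        raise ValueError("n_per_target must be >= 1")
    constraints = constraints or LayoutConstraints()

    for set_try in range(constraints.max_set_tries):
        rng = np.random.default_rng([int(seed), set_try])
        arrangements: list[SceneArrangement] = []
        aid = 0
        for obj in catalog:
            for _ in range(n_per_target):
                arr = _sample_arrangement(catalog, obj.object_id, aid, constraints, rng)
                if arr is None:
                    raise RuntimeError(
                        "arrangement rejection sampling exhausted its retry budget; "
                        "constraints appear infeasible")
                arrangements.append(arr)
                aid += 1
        dists = [cluster_distances(a) for a in arrangements]
        own = float(np.mean([d.delta_T_own_C_cm for d in dists]))
        other = float(np.mean([d.delta_T_other_C_cm for d in dists]))
        if abs(own - other) <= constraints.balance_tol_cm:
            return arrangements
    raise RuntimeError("could not satisfy the cluster-distance balance tolerance")


def generate_practice_arrangements(
    catalog: list[ObjectSpec] | None = None,
    n_trials: int = 12,
    constraints: LayoutConstraints | None = None,
    seed: int = 10_000,
) -> list[SceneArrangement]:
    """Practice layouts (same objects, fresh arrangements); excluded from analysis."""
    n_per_target = int(np.ceil(n_trials / 6))
    arrs = generate_arrangements(catalog, n_per_target, constraints, seed=seed)[:n_trials]
    return [replace(a, arrangement_id=1000 + i) for i, a in enumerate(arrs)]


# ---------------------------------------------------------------------------
# design expansion

def _shift_ok(arrangement, catalog_by_id, shifted, displacements, constraints) -> bool:
    """Shifted objects must stay on the table and clear of all *present* objects.

    The target is absent from the test scene, so its footprint does not
    constrain the shift.
    """
    half_pad = constraints.padding_cm / 2.0
    new_pos = {}
    for oid in shifted:
        x, y = arrangement.positions[oid]
        new_pos[oid] = (x + displacements[oid], y)
    for oid in shifted:
        obj = catalog_by_id[oid]
        rect = _rect(obj, new_pos[oid])
        if (rect[0] < -constraints.table_half_cm or rect[1] > constraints.table_half_cm
                or rect[2] < -constraints.table_half_cm or rect[3] > constraints.table_half_cm):
            return False
        mine = _rect(obj, new_pos[oid], half_pad)
        for other_id, opos in arrangement.positions.items():
            if other_id == oid or other_id == arrangement.target_id:
                continue
            opos2 = new_pos.get(other_id, opos)
            if _rects_overlap(mine, _rect(catalog_by_id[other_id], opos2, half_pad)):
                return False
    return True


def expand_design(
    arrangements: list[SceneArrangement],
    catalog: list[ObjectSpec] | None = None,
    constraints: LayoutConstraints | None = None,
    magnitude_low_cm: float | None = None,
    magnitude_high_cm: float | None = None,
    fixed_magnitude_cm: float | None = None,
    seed: int = 0,
) -> list[TrialCondition]:
    """Expand arrangements into the full design: 1 baseline + 4 shift scenes each.

    Congruent shifts displace the two remaining members of the target's
    cluster; incongruent shifts displace two of the three other-cluster
    objects, counterbalanced over the arrangements of each target. Magnitudes
    are drawn per object from Uniform(magnitude_low, magnitude_high) cm
    (5 cm on average by default) and re-drawn if the shifted scene would be
    invalid; ``fixed_magnitude_cm`` forces a constant magnitude instead.
    """
    catalog = list(catalog) if catalog is not None else generate_catalog()
    constraints = constraints or LayoutConstraints()
    if magnitude_low_cm is None:
        magnitude_low_cm = constraints.shift_low_cm
    if magnitude_high_cm is None:
        magnitude_high_cm = constraints.shift_high_cm
    by_id = {o.object_id: o for o in catalog}
    rng = np.random.default_rng([int(seed), 991])

    # counterbalance the incongruent pair choice over each target's arrangements
    incongruent_pair: dict[int, tuple[str, ...]] = {}
    order: dict[str, list[int]] = {}
    for arr in arrangements:
        order.setdefault(arr.target_id, []).append(arr.arrangement_id)
    for target_id, aids in order.items():
        cluster = arrangements[0].clusters[target_id]
        other = [o.object_id for o in catalog if o.cluster != cluster]
        pairs = list(itertools.combinations(sorted(other), 2))
        perm = rng.permutation(len(pairs))
        for k, aid in enumerate(aids):
            incongruent_pair[aid] = tuple(pairs[perm[k % len(pairs)]])

    conditions: list[TrialCondition] = []
    cid = 0
    for arr in arrangements:
        conditions.append(TrialCondition(cid, arr.arrangement_id, "none", "baseline"))
        cid += 1
        own_pair = tuple(sorted(arr.members(arr.target_cluster, exclude_target=True)))
        for direction in ("left", "right"):
            sign = -1.0 if direction == "left" else 1.0
            for congruence in ("congruent", "incongruent"):
                shifted = own_pair if congruence == "congruent" else incongruent_pair[arr.arrangement_id]
                for _ in range(constraints.max_shift_tries):
                    if fixed_magnitude_cm is not None:
                        mags = [fixed_magnitude_cm] * 2
                    else:
                        mags = rng.uniform(magnitude_low_cm, magnitude_high_cm, size=2)
                    disp = {o: sign * float(m) for o, m in zip(shifted, mags)}
                    if _shift_ok(arr, by_id, shifted, disp, constraints):
                        break
                else:
                    raise RuntimeError(
                        f"arrangement {arr.arrangement_id}: no valid {direction}/"
                        f"{congruence} shift found; arrangement flagged invalid")
                conditions.append(TrialCondition(cid, arr.arrangement_id, direction,
                                                 congruence, shifted, disp))
                cid += 1
    return conditions


def compute_mere(condition: TrialCondition) -> float:
    """Maximal expected reaching error: mean signed displacement of the shifted objects.

    Baseline scenes have no shift; their MERE is defined as 0.
    """
    if condition.congruence == "baseline":
        return 0.0
    return float(np.mean([condition.displacements_cm[o] for o in condition.shifted_ids]))


def cluster_distances(arrangement: SceneArrangement) -> ClusterDistances:
    """dTownC / dTotherC: mean planar target distance to each cluster.

    The target is excluded from its own cluster (2 own vs 3 other members).
    """
    tx, ty = arrangement.target_position

    def mean_dist(ids):
        return float(np.mean([np.hypot(arrangement.positions[o][0] - tx,
                                       arrangement.positions[o][1] - ty) for o in ids]))

    own = arrangement.members(arrangement.target_cluster, exclude_target=True)
    other_cluster = NATURAL if arrangement.target_cluster == MAN_MADE else MAN_MADE
    other = arrangement.members(other_cluster)
    return ClusterDistances(mean_dist(own), mean_dist(other))


def spatial_advantage_correlation(weights, arrangements: list[SceneArrangement]) -> dict:
    """Correlate the spatial advantage of congruence with allocentric weights.

    The advantage (dTotherC - dTownC, averaged over the arrangements whose
    target belongs to a cluster) is paired with each participant's weight for
    that target cluster; Pearson r and two-sided p are computed separately
    for the congruent and incongruent conditions.

    ``weights`` is a weight table as produced by
    :func:`alloreach.allocentric_weights.aggregate_weights`.
    """
    from scipy import stats

    adv: dict[str, float] = {}
    for cluster in CLUSTERS:
        vals = [cluster_distances(a).advantage_cm for a in arrangements
                if a.target_cluster == cluster]
        adv[cluster] = float(np.mean(vals))

    out = {}
    for congruence in ("congruent", "incongruent"):
        sub = weights[(weights["congruence"] == congruence) & weights["weight"].notna()]
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 usable weights for {congruence}")
        x = sub["cluster"].map(adv).to_numpy(float)
        r, p = stats.pearsonr(x, sub["weight"].to_numpy(float))
        out[congruence] = (float(r), float(p))
    return out
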