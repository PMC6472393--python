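import numpy as np
import pytest

import alloreach as ar


@pytest.fixture(scope="session")
def catalog():
    return ar.generate_catalog()


@pytest.fixture(scope="session")
def arrangements():
    return ar.generate_arrangements(seed=1)


@pytest.fixture(scope="session")
def design(arrangements):
    return ar.expand_design(arrangements, seed=1)


@pytest.fixture(scope="session")
def cohort(design, arrangements):
    """One 21-participant cohort at default generator parameters."""
    return ar.simulate_cohort(design, arrangements, n_participants=21, seed=2)


@pytest.fixture(scope="session")
def clean_cohort(cohort):
    clean, report = ar.apply_exclusions(cohort)
    return clean, report


@pytest.fixture(scope="session")
def noiseless_params():
    """Pure allocentric observer: w = 1 everywhere, no noise, no contamination."""
    return ar.GeneratorParams(
        w_congruent=1.0, w_incongruent=1.0, sigma_w=0.0,
        sigma_x_cm=0.0, sigma_y_cm=0.0, bias_x_cm=0.0,
        marker_jitter_cm=0.0, gaze_noise_cm=0.0,
        rate_marker_fail=0.0, rate_premature=0.0, rate_gaze_violation=0.0)


@pytest.fixture(scope="session")
def semantic_space():
    return ar.make_semantic_space(seed=3)


def brute_force_validate(arrangement, catalog, constraints=None):
    """Independent arrangement validator: exhaustive pairwise rectangle test."""
    cons = constraints or ar.LayoutConstraints()
    by_id = {o.object_id: o for o in catalog}

    def rect(oid, inflate=0.0):
        x, y = arrangement.positions[oid]
        o = by_id[oid]
        return (x - o.length_cm / 2 - inflate, x + o.length_cm / 2 + inflate,
                y - o.width_cm / 2 - inflate, y + o.width_cm / 2 + inflate)

    ids = list(arrangement.positions)
    assert len(ids) == 6
    assert arrangement.target_id in ids
    for oid in ids:
        left, right, low, high = rect(oid)
        # inside the table top
        assert left >= -cons.table_half_cm and right <= cons.table_half_cm
        assert low >= -cons.table_half_cm and high <= cons.table_half_cm
        # clear of the central fixation zone (closest rect point vs disc)
        dx = max(left, 0.0, -right)
        dy = max(low, 0.0, -high)
        assert dx * dx + dy * dy >= arrangement.fixation_zone_radius_cm ** 2
    # all 15 pairs keep at least the padding clearance
    half_pad = cons.padding_cm / 2
    for i in range(6):
        for j in range(i + 1, 6):
            a, b = rect(ids[i], half_pad), rect(ids[j], half_pad)
            assert a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2], \
                f"{ids[i]} overlaps {ids[j]}"
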