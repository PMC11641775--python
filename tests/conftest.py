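import numpy as np
import pytest
from hypothesis import settings

from circaplast.records import ActivityRecord, make_light_schedule

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def ld_schedule():
    return make_light_schedule("LD12_12", lights_on_clock=8.0)


@pytest.fixture
def dd_schedule():
    return make_light_schedule("DD", lights_on_clock=8.0)


@pytest.fixture
def toy_record(ld_schedule):
    """12-point hourly series [10,0,0,0] x 3: exact 4-h rhythm."""
    return ActivityRecord(
        "toy", "2024-01-01 08:00", 60.0, np.array([10, 0, 0, 0] * 3, float),
        ld_schedule,
    )


def make_record(counts, bin_minutes=6.0, schedule=None, start="2024-01-01 08:00"):
    if schedule is None:
        schedule = make_light_schedule("LD12_12", lights_on_clock=8.0)
    return ActivityRecord("rec", start, bin_minutes, np.asarray(counts, float), schedule)


def bruteforce_coloc_count(mask_a, mask_b):
    """Exhaustive pixel-scan oracle: overlap pixels grouped by 8-connected
    flood fill (the particle-counting convention), independent of any
    labeling library."""
    overlap = {
        (r, c)
        for r in range(mask_a.shape[0])
        for c in range(mask_a.shape[1])
        if mask_a[r, c] and mask_b[r, c]
    }
    count = 0
    while overlap:
        count += 1
        stack = [overlap.pop()]
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in overlap:
                        overlap.remove(nb)
                        stack.append(nb)
    return count


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def naive_qp(x, p):
    """Independent double-loop chi-square periodogram statistic."""
    x = list(x)
    k = len(x) // p
    n = k * p
    used = x[:n]
    gm = sum(used) / n
    col_means = []
    for h in range(p):
        col = [used[c * p + h] for c in range(k)]
        col_means.append(sum(col) / k)
    sh2 = sum((m - gm) ** 2 for m in col_means) / p
    s2 = sum((v - gm) ** 2 for v in used) / n
    if s2 == 0:
        return 0.0
    return n * sh2 / s2
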