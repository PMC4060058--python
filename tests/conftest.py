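"""Shared fixtures and independent geometry oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from matplotlib.path import Path

from skeletochron.contours import AnnularSection, Contour
from skeletochron.datasets import (load_alligator_measurements,
                                   load_alligator_records,
                                   load_expected_growth_results,
                                   load_expected_paired_results)


@pytest.fixture(scope="session")
def alligator_table():
    return load_alligator_measurements()


@pytest.fixture(scope="session")
def alligator_records():
    """(records, baseline) parsed from the packaged measurement table."""
    return load_alligator_records()


@pytest.fixture(scope="session")
def record_index(alligator_records):
    records, _ = alligator_records
    return {(r.individual_id, r.element, r.side): r for r in records}


@pytest.fixture(scope="session")
def expected_paired():
    return load_expected_paired_results()


@pytest.fixture(scope="session")
def expected_growth():
    return load_expected_growth_results()


# ---------------------------------------------------------------------------
# independent oracles

def regular_ngon(n: int, radius: float = 1.0, center=(0.0, 0.0),
                 phase: float = 0.0, label: str = "surface") -> Contour:
    th = np.linspace(0, 2 * math.pi, n, endpoint=False) + phase
    return Contour(np.column_stack([center[0] + radius * np.cos(th),
                                    center[1] + radius * np.sin(th)]),
                   label=label)


def random_star_polygon(rng: np.random.Generator, radius: float,
                        n: int = 80, wobble: float = 0.12,
                        center=(0.0, 0.0)) -> Contour:
    """Star-convex polygon about ``center`` with bounded radial wobble."""
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    r = np.full(n, radius, dtype=float)
    for j in range(2, 6):
        amp = wobble / j * rng.uniform(0.2, 1.0) * radius
        r += amp * np.cos(j * th + rng.uniform(0, 2 * math.pi))
    return Contour(np.column_stack([center[0] + r * np.cos(th),
                                    center[1] + r * np.sin(th)]))


def random_nested_section(rng: np.random.Generator) -> AnnularSection:
    """Random star-convex annulus (inner strictly inside outer)."""
    outer = random_star_polygon(rng, radius=rng.uniform(1.5, 3.0))
    inner = random_star_polygon(rng, radius=rng.uniform(0.3, 0.7),
                                wobble=0.08)
    return AnnularSection(outer, inner)


def rasterized_moments(section: AnnularSection, h: float = 0.004):
    """Grid-rasterization oracle for annulus centroid and second moments.

    Counts grid-cell centers inside the outer contour and outside the inner
    one; purely numerical, independent of the polygon closed forms.
    """
    v = section.outer.vertices
    x0, y0 = v.min(axis=0) - h
    x1, y1 = v.max(axis=0) + h
    xs = np.arange(x0, x1, h) + h / 2
    ys = np.arange(y0, y1, h) + h / 2
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = Path(section.outer.vertices).contains_points(pts)
    if section.inner is not None:
        mask &= ~Path(section.inner.vertices).contains_points(pts)
    p = pts[mask]
    area = h * h * len(p)
    cx, cy = p.mean(axis=0)
    dx, dy = p[:, 0] - cx, p[:, 1] - cy
    ixx = h * h * np.sum(dy * dy)   # ∫y'² dA
    iyy = h * h * np.sum(dx * dx)
    ixy = h * h * np.sum(dx * dy)
    return area, np.array([cx, cy]), (ixx, iyy, ixy)


def principal_angle(axis: np.ndarray) -> float:
    """Axis direction folded to [0, π) for mod-180° comparison."""
    a = math.atan2(axis[1], axis[0])
    return a % math.pi
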