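"""Shared fixtures: small synthetic cells, standard rates and protocols."""

import numpy as np
import pytest

import optorelease as opt
from optorelease.synthkit import _ellipse_mask


@pytest.fixture(scope="session")
def standard_rates() -> opt.RateParams:
    """Dark-state binding at the reported medians, severalfold lit release."""
    return opt.default_rates()


@pytest.fixture(scope="session")
def standard_schedule() -> opt.LightSchedule:
    return opt.default_protocols("opto-standard")


@pytest.fixture(scope="session")
def small_cell_spec() -> opt.SyntheticCellSpec:
    """A compact cell that keeps rendering and segmentation fast."""
    return opt.SyntheticCellSpec(
        image_shape=(160, 160),
        cell_axes_px=(62.0, 50.0),
        nucleus_axes_px=(21.0, 17.0),
        nucleus_offset_px=(6.0, 5.0),
        seed=1,
    )


@pytest.fixture(scope="session")
def frap_mask_64() -> np.ndarray:
    """Elliptical cytoplasm with a nuclear hole on a 64x64 grid."""
    return _ellipse_mask((64, 64), (32, 32), (28, 24)) & ~_ellipse_mask(
        (64, 64), (32, 32), (10, 8)
    )


@pytest.fixture(scope="session")
def frap_geometry_64(frap_mask_64) -> opt.FRAPGeometry:
    return opt.FRAPGeometry(frap_mask_64, pixel_size_um=0.13)


@pytest.fixture(scope="session")
def frap_protocol_small() -> opt.BleachProtocol:
    """Short acquisition for unit tests: 3 pre-bleach + 30 recovery frames."""
    return opt.BleachProtocol(
        bleach_profile=opt.make_bleach_profile(6, "empirical-like"),
        roi_center=(32, 48),
        roi_radius_px=6,
        frame_interval_s=0.5,
        n_prebleach=3,
        n_recovery=30,
    )


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
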