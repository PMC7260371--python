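"""Shared fixtures: small rendered wells reused across test modules."""

from __future__ import annotations

import pytest

from mitoflux import (
    SegmentationParams,
    SimConfig,
    WellSpec,
    build_cell_rois,
    render_well_image,
    segment_nuclei,
)
from mitoflux.simulate import Noise


@pytest.fixture(scope="session")
def std_well():
    """A 100-cell well with camera noise, mixed mito phenotype (512 px)."""
    spec = WellSpec(well_id="C4", n_cells=25000, frag_prob=0.3)
    cfg = SimConfig(seed=11, wells=[spec], image_size_px=(512, 512),
                    field_fraction=0.004, noise=Noise())
    img, truth = render_well_image(spec, cfg)
    return spec, cfg, img, truth


@pytest.fixture(scope="session")
def std_segmentation(std_well):
    _, _, img, _ = std_well
    return segment_nuclei(img)


@pytest.fixture(scope="session")
def std_rois(std_well, std_segmentation):
    _, _, img, _ = std_well
    return build_cell_rois(std_segmentation, img)


@pytest.fixture(scope="session")
def noise_off_well():
    """An 80-cell well with noise disabled (pixel-sum oracles are exact)."""
    spec = WellSpec(well_id="D5", n_cells=20000, frag_prob=0.4)
    cfg = SimConfig(seed=13, wells=[spec], image_size_px=(512, 512),
                    field_fraction=0.004, noise=Noise.off(background_level=100.0))
    img, truth = render_well_image(spec, cfg)
    return spec, cfg, img, truth


@pytest.fixture(scope="session")
def noise_off_segmentation(noise_off_well):
    _, _, img, _ = noise_off_well
    return segment_nuclei(img)


@pytest.fixture(scope="session")
def noise_off_rois(noise_off_well, noise_off_segmentation):
    _, _, img, _ = noise_off_well
    return build_cell_rois(noise_off_segmentation, img)
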