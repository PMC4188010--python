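"""End-to-end droplet processing.

Ties the stages together: greyscale/contrast normalization, well
registration and fault screening, droplet segmentation with fallbacks,
shadow gamma correction, boundary extension, intensity standardization and
downscaling, filter-bank responses, texton labelling and the final
histogram descriptor.  Also builds the shipped reference texton dictionary
from the seeded synthetic training sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import preprocess, synthetic
from .filterbank import FilterBank, apply_filter_bank, build_filter_bank
from .segmentation import BackgroundModel, register_well, segment_droplet
from .textons import (
    DEFAULT_DICT_SIZE,
    DEFAULT_LAMBDA,
    TextonDictionary,
    build_dictionary,
    label_pixels,
    texton_histogram,
)

__all__ = [
    "PipelineConfig",
    "droplet_descriptor",
    "descriptor_from_mask",
    "process_well_image",
    "build_reference_dictionary",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Imager-level knobs.

    filter_scale scales the filter-bank sigmas (0.5 = the half-scale bank);
    image_scale matches new images to the dictionary resolution (0.25 for
    the reference imager, 0.5 for higher-magnification imagers); gamma_sigma
    is the low-pass width of the shadow correction, with the larger
    fallback_gamma_sigma used only when segmentation needs rescuing.
    """

    filter_scale: float = 0.5
    image_scale: float = 0.25
    gamma_sigma: float = 1.0
    fallback_gamma_sigma: float = 10.0
    max_shift: int = 10
    dict_size: int = DEFAULT_DICT_SIZE
    dp_lambda: float = DEFAULT_LAMBDA
    seed: int = 0
    _bank: FilterBank | None = field(default=None, repr=False)

    @property
    def bank(self) -> FilterBank:
        if self._bank is None:
            self._bank = build_filter_bank(self.filter_scale)
        return self._bank


def descriptor_from_mask(
    image: np.ndarray,
    droplet_mask: np.ndarray,
    dictionary: TextonDictionary,
    config: PipelineConfig | None = None,
):
    """Texton histogram of a droplet given its mask.

    Runs the texture stages only (gamma correction, boundary extension,
    standardize + downscale, filter, label, count); segmentation/fault
    screening are assumed done.  Returns (TextonHistogram, TextonMap).
    """
    config = config or PipelineConfig()
    grey = preprocess.to_grey_full_range(image)
    corrected = preprocess.gamma_correct(
        grey, mask=droplet_mask, sigma=config.gamma_sigma
    )
    ext = preprocess.extend_boundary(corrected, droplet_mask)
    proc = preprocess.normalize_and_scale(
        ext.image, ext.droplet_mask, scale=config.image_scale,
        ring_mask=ext.ring_mask,
    )
    resp = apply_filter_bank(proc.image, config.bank)
    count_mask = proc.valid_mask & ~proc.ring_mask
    tmap = label_pixels(resp, dictionary, count_mask)
    hist = texton_histogram(tmap, len(dictionary))
    return hist, tmap


def process_well_image(
    image: np.ndarray,
    subwell,
    bg: BackgroundModel,
    dictionary: TextonDictionary,
    config: PipelineConfig | None = None,
    fault_model=None,
):
    """Full pipeline for one raw well image.

    Returns a dict with keys status ('ok', 'faulty' or 'unsegmentable'),
    histogram, registration, boundary and fault probability.
    """
    from .faults import fault_features, predict_fault

    config = config or PipelineConfig()
    grey = preprocess.to_grey_full_range(image)
    background = bg.background(subwell)
    frame = bg.frame_mask(subwell)
    reg = register_well(grey, background, max_shift=config.max_shift)
    boundary = segment_droplet(
        grey, reg, background, frame,
        fallback_gamma_sigma=config.fallback_gamma_sigma,
    )

    result = {
        "status": "ok",
        "registration": reg,
        "boundary": boundary,
        "p_faulty": None,
        "histogram": None,
    }
    if fault_model is not None:
        feats = fault_features(grey, reg, frame, boundary)
        pred = predict_fault(fault_model, [feats])
        result["p_faulty"] = float(pred["p_faulty"].iloc[0])
        if pred["verdict"].iloc[0] == "faulty":
            result["status"] = "faulty"
            return result
    if boundary is None:
        result["status"] = "unsegmentable"
        return result
    hist, _ = descriptor_from_mask(grey, boundary.mask, dictionary, config)
    result["histogram"] = hist
    return result


def _training_responses(wells, config, kind):
    """Per-image droplet response matrices at the dictionary resolution."""
    resp_list, mask_list = [], []
    for img, truth in wells:
        grey = preprocess.to_grey_full_range(img)
        corrected = preprocess.gamma_correct(
            grey, mask=truth.droplet_mask, sigma=config.gamma_sigma
        )
        ext = preprocess.extend_boundary(corrected, truth.droplet_mask)
        crys = truth.crystal_mask[
            ext.origin[0] : ext.origin[0] + ext.image.shape[0],
            ext.origin[1] : ext.origin[1] + ext.image.shape[1],
        ]
        proc = preprocess.normalize_and_scale(
            ext.image, ext.droplet_mask, scale=config.image_scale,
            ring_mask=ext.ring_mask,
        )
        from skimage.transform import rescale

        crys_s = rescale(crys.astype(float), config.image_scale, order=0) >= 0.5
        resp = apply_filter_bank(proc.image, config.bank)
        use = resp.valid & proc.valid_mask & ~proc.ring_mask
        resp_list.append(resp.responses[use])
        if kind == "crystal":
            mask_list.append(crys_s[use])
    return resp_list, mask_list


def build_reference_dictionary(
    seed: int = 0,
    config: PipelineConfig | None = None,
    n_precipitate: int = 100,
    n_crystal: int = 52,
    target_size: int | None = DEFAULT_DICT_SIZE,
) -> TextonDictionary:
    """Build the default texton dictionary from the seeded synthetic sets.

    100 precipitation wells and 52 crystal-containing wells (with
    ground-truth crystal masks) are processed to droplet response matrices;
    the two-stage clustering with size calibration yields the
    ``target_size``-entry dictionary.
    """
    config = config or PipelineConfig(seed=seed)
    precip, crystal = synthetic.dictionary_training_set(
        n_precipitate, n_crystal, seed=seed
    )
    log.info("clustering %d precipitate images", len(precip))
    p_resp, _ = _training_responses(precip, config, "precipitate")
    log.info("clustering %d crystal images", len(crystal))
    c_resp, c_mask = _training_responses(crystal, config, "crystal")
    return build_dictionary(
        p_resp, c_resp, c_mask,
        lam=config.dp_lambda, target_size=target_size, seed=seed,
    )
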