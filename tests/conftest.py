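"""Shared fixtures: small synthetic scenes and a once-trained classifier.

Everything is generated programmatically at test time; the scales are kept
small (256-384 px frames, a dozen polyps, one or two training epochs) so the
whole suite stays desk-sized while still exercising the real code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coralwatch import polyps as pl
from coralwatch import synth


@pytest.fixture(scope="session")
def small_scene():
    """A static 320x320 scene: coral region + 14 polyp centres."""
    region, centres = synth.generate_scene((320, 320), n_polyps=14, seed=5)
    return region, centres


@pytest.fixture(scope="session")
def small_sequence(small_scene):
    """10 frames over the small scene with an activity ramp and no jitter."""
    frames, truths = synth.generate_sequence(
        10, 5.0, np.linspace(0.15, 0.85, 10), jitter_sd=0.0,
        missing_fraction=0.0, seed=5, shape=(320, 320), n_polyps=14)
    return frames, truths


@pytest.fixture(scope="session")
def annotated_patches(small_sequence):
    """Split + augmented patch set from 4 annotated frames of the sequence."""
    frames, truths = small_sequence
    ids = [str(i) for i in range(4)]
    ann = synth.generate_annotations(truths[:4], seed=0, image_ids=ids)
    ann.index = np.arange(len(ann))
    mask = pl.build_polyp_mask(ann[ann.image == "0"], frames[0].pixels.shape[:2])
    sets = [pl.extract_patches(frames[i], ann[ann.image == ids[i]], image_id=ids[i])
            for i in range(4)]
    sets.append(pl.sample_background(frames[0], mask, n=40, seed=1))
    ps = pl.split_dataset(pl.PatchSet.concat(sets), seed=2)
    return pl.augment_patches(ps, seed=3), mask, ann


@pytest.fixture(scope="session")
def trained_classifier(annotated_patches):
    """A LeNet trained once on the small synthetic patch set."""
    augmented, mask, ann = annotated_patches
    clf = pl.train_classifier(augmented, pl.TrainSpec(epochs=2, seed=0))
    return clf, mask
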