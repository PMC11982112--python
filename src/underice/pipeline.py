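"""End-to-end helpers chaining the pipeline stages on in-memory campaigns."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from . import classification, imaging


def extract_campaign_features(images: dict, pixel_scale_um: float = 1.0) -> pd.DataFrame:
    """Segment every ROI and extract the feature table (index image_id)."""
    return imaging.extract_features_table(images, pixel_scale_um=pixel_scale_um)


def training_database(features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Join a feature table with per-image category labels."""
    db = features.copy()
    db.insert(0, "category", labels.loc[db.index])
    return db


def classify_campaign(features: pd.DataFrame, manifest: pd.DataFrame,
                      model, vote_threshold: float = classification.DEFAULT_VOTE_THRESHOLD,
                      small_image_class: Optional[str] = "Urosolenia",
                      small_image_threshold_um3: float = imaging.UROSOLENIA_BIOVOLUME_CUT_UM3,
                      ) -> pd.DataFrame:
    """Classify campaign images and build filtered biovolume records.

    Returns one row per retained image: sample_id, image_id, class,
    biovolume_um3. The small-image filter is applied post-classification to
    ``small_image_class`` only (pass ``None`` to skip it).
    """
    result = classification.classify(model, features, vote_threshold)
    records = pd.DataFrame({
        "image_id": features.index,
        "sample_id": manifest.set_index("image_id").loc[features.index, "sample_id"].to_numpy(),
        "class": result["label"].to_numpy(),
        "biovolume_um3": features["biovolume_um3"].to_numpy(),
    })[["sample_id", "image_id", "class", "biovolume_um3"]]
    if small_image_class is not None:
        records = imaging.filter_small_images(records, small_image_class,
                                              small_image_threshold_um3)
    return records.reset_index(drop=True)
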