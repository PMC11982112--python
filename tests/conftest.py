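"""Shared fixtures: one full synthetic-season pipeline run, reused by the
end-to-end tests so the expensive rendering/feature-extraction happens once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from underice import classification as cl
from underice import imaging, pipeline
from underice import synthetic_data as sd

SEASON_DAYS = 28.0
SEASON_START = pd.Timestamp("2015-01-05")
DEPTHS = (2.0, 4.0, 10.0)
SAMPLE_PERIOD_MIN = 720.0  # 12-h cadence keeps the suite fast at n>=40/depth
TRAIN_PER_CATEGORY = 230
CAMPAIGN_SEED = 7
TRAIN_SEED = 11


@pytest.fixture(scope="session")
def season_taxa():
    return sd.default_taxa(SEASON_DAYS)


@pytest.fixture(scope="session")
def season_campaign(season_taxa):
    """Synthetic winter campaign: 3 depths × 56 samples at 12-h cadence."""
    config = sd.CampaignConfig(
        start=SEASON_START, end=SEASON_START + pd.Timedelta(days=SEASON_DAYS),
        depths_m=DEPTHS, periods_min=(SAMPLE_PERIOD_MIN,) * len(DEPTHS),
        rng_seed=CAMPAIGN_SEED)
    data = sd.generate_campaign(config, sd.scenario_stable_winter(), season_taxa)
    return config, data


@pytest.fixture(scope="session")
def training_database(season_taxa):
    """Feature database from labelled ROIs rendered per category."""
    rng = np.random.default_rng(TRAIN_SEED)
    images, labels = {}, {}
    for taxon in season_taxa:
        for i in range(TRAIN_PER_CATEGORY):
            image, cls, _ = sd.generate_roi(taxon, rng)
            image_id = f"train_{cls}_{i:04d}"
            images[image_id] = image
            labels[image_id] = cls
    features = imaging.extract_features_table(images)
    return pipeline.training_database(features, pd.Series(labels))


@pytest.fixture(scope="session")
def best_classifier(training_database):
    """Winner of a reduced selection grid on the synthetic morphotypes."""
    grid = cl.enumerate_grid((120, 150), (180, 200), (25, 50))
    candidates = cl.run_grid(training_database, grid, seed=3)
    return cl.select_best(candidates)


@pytest.fixture(scope="session")
def season_pipeline(season_campaign, best_classifier):
    """Classified, filtered biovolume records + per-mL series for the season."""
    from underice import timeseries as ts

    config, data = season_campaign
    features = pipeline.extract_campaign_features(data.images,
                                                  data.pixel_scale_um)
    records = pipeline.classify_campaign(features, data.manifest,
                                         best_classifier.model)
    series = ts.aggregate_campaign(records, data.samples)
    smooth = ts.moving_average(series)
    return {"config": config, "data": data, "features": features,
            "records": records, "series": series, "smooth": smooth}
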