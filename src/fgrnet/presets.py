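"""Ready-made configuration bundles.

``default_*`` are the full-size settings; ``desk_*`` are reduced widths and
epoch budgets sized so a complete repeated cross-validation runs in minutes
on a single laptop core while preserving every architectural element.  The
desk preset is what the bundled evaluation scripts use.
"""

from __future__ import annotations

from .correlation import CnetConfig, ResidualExtractorConfig
from .embedding import EmbedConfig
from .predictor import HeadConfig, PredictorConfig


def default_predictor_config(**overrides) -> PredictorConfig:
    return PredictorConfig(**overrides)


def default_embed_config(**overrides) -> EmbedConfig:
    return EmbedConfig(**overrides)


def desk_predictor_config(**overrides) -> PredictorConfig:
    # pool_size 1: on ~100-sample profiles the pair head needs per-sample
    # alignment, which max-pooling destroys (see docs/methods.md)
    cfg = PredictorConfig(
        extractor=ResidualExtractorConfig(channels=(4, 6, 8), pool_size=1,
                                          output_dim=16),
        cnet=CnetConfig(hidden_dim=128, d_corr=32),
        head=HeadConfig(channels=16, hidden_dim=32),
        embed_dim=16,
        batch_size=32,
        max_epochs=100,
        patience=15,
        early_stop_metric="auc",
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def desk_embed_config(**overrides) -> EmbedConfig:
    cfg = EmbedConfig(d=16, epochs=20, batch_size=128)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
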