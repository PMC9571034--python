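"""End-to-end synthetic study: simulate -> montage -> features ->
selection -> train/evaluate -> diagnose, with every artifact on disk."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .config import RunConfig
from .dataset import feature_table, training_sequences
from .diagnosis import diagnose_population
from .features import FEATURE_NAMES
from .model import ChannelSequenceClassifier, NetworkConfig, evaluate
from .montage import compute_lb
from .selection import FeatureGroup, build_feature_groups, correlation_screen
from .simulate import simulate_population

logger = logging.getLogger("epichannel")

#: Groups used when the data-driven screen cannot assemble 5-feature
#: groups (e.g. too few label-significant features at small n).
CANONICAL_GROUPS = [
    FeatureGroup("group-1", ("mean", "min", "skew", "kurt", "theta")),
    FeatureGroup("group-2", ("mean", "min", "skew", "kurt", "alpha")),
    FeatureGroup("group-3", ("mean", "min", "skew", "kurt", "beta")),
]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline and write its artifacts under ``out_dir``.

    Returns a dict with the selection report, per-group evaluation, the
    chosen feature group, and the diagnosis of the simulated focal and
    generalized populations.  Rerunning with the same config and seed
    reproduces every JSON artifact byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31 - 1)
    stage = "simulate"
    try:
        populations = {
            group: simulate_population(
                config.n_subjects_per_group,
                group,
                config.simulation,
                seed=int(seeds[i]),
            )
            for i, group in enumerate(("normal", "focal", "generalized"))
        }
        stage = "montage"
        bipolar = {
            group: [compute_lb(rec) for rec in recs]
            for group, recs in populations.items()
        }
        chain_kwargs = dict(
            denoise_config=config.denoise,
            window_s=config.window_s,
            overlap_fraction=config.overlap_fraction,
        )
        stage = "features"
        train_seqs = training_sequences(
            bipolar["focal"],
            bipolar["normal"],
            feature_subset=FEATURE_NAMES,
            **chain_kwargs,
        )
        table = feature_table(train_seqs)
        table.to_csv(out / "features.csv", index=False)

        stage = "selection"
        report = correlation_screen(table[list(FEATURE_NAMES)], table["label"])
        r_frame, p_frame, class_frame = report.to_frames()
        r_frame.to_csv(out / "correlation_r.csv")
        p_frame.to_csv(out / "correlation_p.csv")
        class_frame.to_csv(out / "class_association.csv")
        try:
            groups = build_feature_groups(
                report,
                alpha=config.alpha,
                low_thr=config.low_thr,
                high_thr=config.high_thr,
            )
            selection_mode = "screened"
        except ValueError as exc:
            logger.warning(
                "feature screen could not assemble groups (%s); "
                "falling back to the canonical band-power groups",
                exc,
            )
            groups = CANONICAL_GROUPS
            selection_mode = "canonical_fallback"
        selection_report = {
            "mode": selection_mode,
            "kept": [
                name
                for name, p in zip(report.feature_names, report.class_p)
                if p < config.alpha
            ],
            "groups": {g.name: list(g.members) for g in groups},
        }
        _dump_json(selection_report, out / "selection.json")

        stage = "evaluate"
        evaluations = {}
        for i, group in enumerate(groups):
            seqs = training_sequences(
                bipolar["focal"],
                bipolar["normal"],
                feature_subset=group.members,
                **chain_kwargs,
            )
            evaluations[group.name] = evaluate(
                seqs,
                config=config.network,
                n_splits=config.n_splits,
                test_fraction=config.test_fraction,
                seed=int(seeds[3 + (i % 4)]),
            )
        performance = {
            name: rep.to_dict() for name, rep in evaluations.items()
        }
        _dump_json(performance, out / "performance.json")
        best_name = max(
            evaluations, key=lambda k: evaluations[k].metrics["accuracy"]
        )
        best_group = next(g for g in groups if g.name == best_name)

        stage = "train"
        final_seqs = training_sequences(
            bipolar["focal"],
            bipolar["normal"],
            feature_subset=best_group.members,
            **chain_kwargs,
        )
        final_config = NetworkConfig(
            **{**asdict(config.network), "seed": int(seeds[7])}
        )
        results = ChannelSequenceClassifier(final_seqs, final_config).fit()
        results.save(out / "model.npz")

        stage = "diagnose"
        diagnosis = {}
        profile_rows = []
        for group in ("focal", "generalized"):
            result, profile = diagnose_population(
                results,
                bipolar[group],
                threshold=config.diagnosis_threshold,
                **chain_kwargs,
            )
            diagnosis[group] = result.to_dict()
            for ch, pct in zip(profile.channel_labels, profile.percentages):
                profile_rows.append(f"{ch},{group},{pct:.6f}")
        _dump_json(diagnosis, out / "diagnosis.json")
        (out / "profiles.csv").write_text(
            "channel,group,percentage\n" + "\n".join(profile_rows) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    run_info = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "best_group": best_name,
        "best_members": list(best_group.members),
    }
    _dump_json(run_info, out / "run.json")
    return {
        "selection": selection_report,
        "performance": performance,
        "best_group": best_name,
        "best_members": list(best_group.members),
        "diagnosis": diagnosis,
    }
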