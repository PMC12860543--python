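"""End-to-end synthetic observer study.

Orchestrates: training cohort -> scatter/photopeak reconstructions ->
segmentation-network training -> test cohort -> projection-domain defect
insertion -> three reconstruction arms -> channelized Hotelling observer ->
cluster-aware statistics -> report.

The three arms are

* ``true_mu`` — attenuation compensation with the phantom's true attenuation
  map (the synthetic analog of CT-based AC; there is no CT in this study),
* ``ctless``  — AC with the attenuation map assembled from the network's
  segmentation of the scatter- and photopeak-window reconstructions,
* ``nac``     — no attenuation compensation.

Defect-absent subjects contribute one reconstruction per arm but 27
bookkeeping replicates (one per defect type, ROI centered at that type's
centroid); the cluster-aware variance treats each subject as a single unit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .defects import DefectSpec, defect_centroid, enumerate_defect_types, insert_defect
from .mumap import assemble_mu
from .observer import apply_channels, grouped_loo_scores, make_rsf_channels, roc_auc
from .phantom import MUSCLE, LUNG, CoefficientTable, PhantomParams, VariabilityParams, generate_phantom
from .projector import (
    AcquisitionGeometry,
    SpectProjector,
    add_poisson_noise,
    make_projection_set,
)
from .recon import butterworth_filter, extract_cardiac_roi, osem
from .segnet import McEUN, TrainConfig, dice_coefficient, predict_segments, train_mceun
from .stats import (
    auc_ci_correlated,
    bootstrap_diff,
    fidelity_metrics,
    noninferiority_test,
    paired_auc_difference,
)

log = logging.getLogger(__name__)

ARMS = ("true_mu", "ctless", "nac")


@dataclass
class StudyConfig:
    """Desk-scale study conditions (defaults sized for a single CPU)."""

    grid: int = 64
    voxel_size: float = 0.68
    n_train: int = 8
    n_test_present: int = 7
    n_test_absent: int = 7
    seed: int = 0
    target_counts: float = 2.0e6       # total photopeak counts per acquisition
    n_iterations: int = 8
    n_subsets: int = 6
    epochs: int = 160
    base_filters: int = 4
    lr: float = 2e-3
    batch_size: int = 4
    margin_frac: float = 0.05
    alpha: float = 0.05
    bootstrap_B: int = 1000
    mu_per_sample: bool = False
    recon_dtype: str = "float32"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def build_test_set(n_present: int, n_absent: int, seed: int = 0,
                   defect_types: list[DefectSpec] | None = None,
                   exclude_subject_ids: set | None = None) -> pd.DataFrame:
    """Sample manifest for the test study.

    Every defect-present subject is crossed with all defect types; every
    defect-absent subject contributes one replicate entry per defect type,
    all sharing the subject's cluster id (the underlying acquisition is
    identical).  Raises if a generated subject id collides with
    ``exclude_subject_ids`` (test/training separation).
    """
    if n_present < 1 or n_absent < 1:
        raise ValueError("need at least one subject per class")
    specs = defect_types or enumerate_defect_types()
    ss = np.random.SeedSequence(seed)
    pres_seeds = ss.spawn(1)[0].generate_state(n_present) % (2**31 - 1)
    abs_seeds = ss.spawn(2)[1].generate_state(n_absent) % (2**31 - 1)
    rows = []
    for i, s in enumerate(pres_seeds):
        sid = f"present-{seed}-{i:04d}"
        for spec in specs:
            rows.append(dict(sample_id=f"{sid}/{spec.key()}", subject_id=sid,
                             cluster_id=sid, label=1, subject_seed=int(s),
                             extent_deg=spec.extent_deg,
                             severity_frac=spec.severity_frac,
                             location=spec.location, defect_key=spec.key()))
    for i, s in enumerate(abs_seeds):
        sid = f"absent-{seed}-{i:04d}"
        for spec in specs:
            rows.append(dict(sample_id=f"{sid}/{spec.key()}", subject_id=sid,
                             cluster_id=sid, label=0, subject_seed=int(s),
                             extent_deg=spec.extent_deg,
                             severity_frac=spec.severity_frac,
                             location=spec.location, defect_key=spec.key()))
    df = pd.DataFrame(rows)
    if exclude_subject_ids and set(df.subject_id) & set(exclude_subject_ids):
        raise ValueError("test subjects overlap training subjects")
    return df


# ---------------------------------------------------------------------------
# study stages
# ---------------------------------------------------------------------------

def _phantom_params(config: StudyConfig) -> PhantomParams:
    return PhantomParams.for_grid(config.grid, config.voxel_size,
                                  variability=VariabilityParams())


def _noisy_windows(phantom, geometry, config):
    """Noise-free projections plus the per-subject count scale."""
    proj = make_projection_set(phantom, geometry=geometry)
    count_scale = config.target_counts / float(proj.photopeak.sum())
    return proj, count_scale


def _recon(sino, projector, config) -> np.ndarray:
    return osem(sino, projector, config.n_iterations, config.n_subsets)


def prepare_training_set(config: StudyConfig, progress: bool = False):
    """Reconstruct NAC scatter/photopeak pairs for the training cohort."""
    params = _phantom_params(config)
    geometry = AcquisitionGeometry(n_bins=config.grid, bin_size_cm=config.voxel_size)
    dtype = np.dtype(config.recon_dtype)
    ss = np.random.SeedSequence([config.seed, 101])
    subj_seeds = ss.generate_state(config.n_train) % (2**31 - 1)
    noise_seeds = ss.spawn(config.n_train)
    dataset, subject_ids = [], []
    proj_nac = SpectProjector(geometry, config.grid, config.voxel_size,
                              mu=None, model_cdr=True, dtype=dtype)
    for i, s in enumerate(subj_seeds):
        ph = generate_phantom(params, seed=int(s))
        ph.subject_id = f"train-{config.seed}-{i:04d}"
        subject_ids.append(ph.subject_id)
        proj, count_scale = _noisy_windows(ph, geometry, config)
        noisy = add_poisson_noise(proj, count_scale, int(noise_seeds[i].generate_state(1)[0] % (2**31 - 1)))
        f_sc = _recon(noisy.scatter, proj_nac, config)
        f_pp = _recon(noisy.photopeak, proj_nac, config)
        dataset.append((f_sc, f_pp, ph.labels))
        if progress:
            log.info("training subject %d/%d reconstructed", i + 1, config.n_train)
    return dataset, subject_ids


def train_network(config: StudyConfig, dataset=None, progress: bool = False):
    """Train the segmentation network on the study's training cohort."""
    if dataset is None:
        dataset, _ = prepare_training_set(config, progress=progress)
    tc = TrainConfig(epochs=config.epochs, lr=config.lr, batch_size=config.batch_size,
                     base_filters=config.base_filters, seed=config.seed)
    net, history = train_mceun(dataset, tc)
    return net, history


def _arm_volumes_for_subject(ph, geometry, config, net, specs, noise_seed,
                             present: bool, channels, table):
    """Reconstruct all samples of one subject for the three arms.

    Returns (features per arm per sample, per-subject diagnostics).
    """
    dtype = np.dtype(config.recon_dtype)
    n = config.grid
    rc = config
    proj, count_scale = _noisy_windows(ph, geometry, config)
    proj_mu = SpectProjector(geometry, n, ph.voxel_size, mu=ph.mu,
                             model_cdr=True, dtype=dtype)
    proj_nac = SpectProjector(geometry, n, ph.voxel_size, mu=None,
                              model_cdr=True, dtype=dtype)

    ss = np.random.SeedSequence([noise_seed, 7])
    seeds = ss.generate_state(len(specs) + 2) % (2**31 - 1)

    # scatter window: one realization per subject (defects never touch it)
    sc_noisy = add_poisson_noise(proj.scatter, count_scale, int(seeds[-1]))
    f_sc = _recon(sc_noisy, proj_nac, rc)

    # defect-free photopeak sample (always needed: mu-hat inputs + fidelity)
    pp0_noisy = add_poisson_noise(proj.photopeak, count_scale, int(seeds[-2]))
    f_pp0_nac = _recon(pp0_noisy, proj_nac, rc)

    seg = predict_segments(f_sc / max(f_sc.max(), 1e-12),
                           f_pp0_nac / max(f_pp0_nac.max(), 1e-12), net)
    mu_hat = assemble_mu(seg, table).mu_hat
    proj_ctless = SpectProjector(geometry, n, ph.voxel_size, mu=mu_hat,
                                 model_cdr=True, dtype=dtype)

    if present:
        sinos = []
        for k, spec in enumerate(specs):
            defected = insert_defect(proj, ph, spec, projector=proj_mu)
            sinos.append(add_poisson_noise(defected.photopeak, count_scale, int(seeds[k])))
        # per-sample loops: on one CPU they outrun batched linear algebra
        vols = {
            "nac": np.stack([osem(s, proj_nac, rc.n_iterations, rc.n_subsets)
                             for s in sinos]),
            "true_mu": np.stack([osem(s, proj_mu, rc.n_iterations, rc.n_subsets)
                                 for s in sinos]),
        }
        if config.mu_per_sample:
            # a fresh attenuation map from each sample's own photopeak recon
            ctless = []
            for k in range(len(specs)):
                seg_k = predict_segments(
                    f_sc / max(f_sc.max(), 1e-12),
                    vols["nac"][k] / max(vols["nac"][k].max(), 1e-12), net)
                mu_k = assemble_mu(seg_k, table).mu_hat
                pj = SpectProjector(geometry, n, ph.voxel_size, mu=mu_k,
                                    model_cdr=True, dtype=dtype)
                ctless.append(osem(sinos[k], pj, rc.n_iterations, rc.n_subsets))
            vols["ctless"] = np.stack(ctless)
        else:
            vols["ctless"] = np.stack([osem(s, proj_ctless, rc.n_iterations, rc.n_subsets)
                                       for s in sinos])
    else:
        base = {
            "nac": f_pp0_nac,
            "true_mu": _recon(pp0_noisy, proj_mu, rc),
            "ctless": _recon(pp0_noisy, proj_ctless, rc),
        }
        vols = {arm: np.repeat(base[arm][None], len(specs), axis=0) for arm in ARMS}

    # fidelity volumes: defect-free reconstruction per arm (filtered)
    fid = {
        "nac": f_pp0_nac,
        "true_mu": _recon(pp0_noisy, proj_mu, rc) if present else vols["true_mu"][0],
        "ctless": _recon(pp0_noisy, proj_ctless, rc) if present else vols["ctless"][0],
    }
    fid = {arm: butterworth_filter(v, voxel_size_cm=ph.voxel_size) for arm, v in fid.items()}

    lv_mask = ph.lv_wall_mask()
    feats = {arm: [] for arm in ARMS}
    for k, spec in enumerate(specs):
        centroid = defect_centroid(ph, spec)
        for arm in ARMS:
            vol = butterworth_filter(vols[arm][k], voxel_size_cm=ph.voxel_size)
            roi = extract_cardiac_roi(vol, centroid, lv_mask)
            feats[arm].append(apply_channels(roi, channels))

    diag = {
        "mu_rmse_ctless": float(np.sqrt(np.mean((mu_hat - ph.mu) ** 2))),
        "mu_rmse_zero": float(np.sqrt(np.mean(ph.mu**2))),
        "dice_muscles": dice_coefficient(seg.labels == MUSCLE, ph.labels == MUSCLE),
        "dice_lungs": dice_coefficient(seg.labels == LUNG, ph.labels == LUNG),
        "fidelity": {
            arm: fidelity_metrics(fid[arm], fid["true_mu"]) for arm in ("ctless", "nac")
        },
    }
    return {arm: np.asarray(f) for arm, f in feats.items()}, diag


def run_experiment(config: StudyConfig, net: McEUN | None = None,
                   out_dir=None, progress: bool = False) -> dict:
    """Run the full synthetic observer study and return the report.

    Stages: (1) train the segmentation network on its own cohort (skipped
    when ``net`` is supplied); (2) build the test manifest; (3) simulate,
    insert defects, reconstruct three arms, extract ROIs and channel
    features; (4) observer scoring (leave-one-out CHO) and statistics.
    Every source of randomness derives from ``config.seed``.
    """
    t0 = time.time()
    stage = "train"
    try:
        train_ids: list = []
        if net is None:
            dataset, train_ids = prepare_training_set(config, progress=progress)
            net, _ = train_network(config, dataset=dataset, progress=progress)

        stage = "manifest"
        specs = enumerate_defect_types()
        manifest = build_test_set(config.n_test_present, config.n_test_absent,
                                  seed=config.seed + 1,
                                  exclude_subject_ids=set(train_ids))

        stage = "simulate"
        params = _phantom_params(config)
        geometry = AcquisitionGeometry(n_bins=config.grid, bin_size_cm=config.voxel_size)
        channels = make_rsf_channels(grid=32, pixel_cm=config.voxel_size)
        table = CoefficientTable.default()

        subjects = manifest.drop_duplicates("subject_id")[
            ["subject_id", "subject_seed", "label"]].reset_index(drop=True)
        feats = {arm: [] for arm in ARMS}
        rows = []
        diags = []
        for si, subj in subjects.iterrows():
            ph = generate_phantom(params, seed=int(subj.subject_seed))
            ph.subject_id = subj.subject_id
            f, diag = _arm_volumes_for_subject(
                ph, geometry, config, net, specs, noise_seed=int(subj.subject_seed),
                present=bool(subj.label), channels=channels, table=table)
            diag["subject_id"] = subj.subject_id
            diag["label"] = int(subj.label)
            diags.append(diag)
            for arm in ARMS:
                feats[arm].append(f[arm])
            sub_rows = manifest[manifest.subject_id == subj.subject_id]
            rows.append(sub_rows)
            if progress:
                log.info("subject %d/%d done (%.1fs elapsed)",
                         si + 1, len(subjects), time.time() - t0)
        manifest = pd.concat(rows, ignore_index=True)
        features = {arm: np.concatenate(feats[arm], axis=0) for arm in ARMS}

        stage = "observer"
        labels = manifest.label.to_numpy()
        clusters = manifest.cluster_id.to_numpy()
        locations = manifest.location.to_numpy()
        scores, aucs = {}, {}
        for arm in ARMS:
            scores[arm] = grouped_loo_scores(features[arm], labels, locations)
            aucs[arm] = auc_ci_correlated(scores[arm], labels, clusters,
                                          alpha=config.alpha)

        stage = "stats"
        d_ct, var_ct, ci_ct = paired_auc_difference(
            scores["ctless"], scores["true_mu"], labels, clusters, alpha=config.alpha)
        ni = noninferiority_test(aucs["ctless"].auc, aucs["true_mu"].auc, var_ct,
                                 margin_frac=config.margin_frac, alpha=config.alpha)
        comparisons = {"ctless_vs_true_mu": {
            "delta_auc": d_ct, "ci": ci_ct, "margin": ni.margin,
            "decision": ni.decision, "p_noninferiority": ni.p_noninferiority}}
        for arm in ("ctless", "true_mu"):
            d, var, ci = paired_auc_difference(scores[arm], scores["nac"],
                                               labels, clusters, alpha=config.alpha)
            res = noninferiority_test(aucs[arm].auc, aucs["nac"].auc, var,
                                      margin_frac=config.margin_frac,
                                      alpha=config.alpha, n_comparisons=2)
            comparisons[f"{arm}_vs_nac"] = {
                "delta_auc": d, "ci": ci,
                "p_superiority": res.p_superiority,
                "p_superiority_adjusted": res.p_superiority_adjusted,
                "superior": res.ci[0] > 0,
            }

        strat = {}
        for ext in sorted(manifest.extent_deg.unique()):
            for sev in sorted(manifest.severity_frac.unique()):
                sel = ((manifest.extent_deg == ext) & (manifest.severity_frac == sev)).to_numpy()
                cell = {}
                for arm in ARMS:
                    cell[arm] = float(roc_auc(scores[arm][sel], labels[sel]).auc)
                strat[f"extent{int(ext)}_sev{int(round(sev * 100))}"] = cell

        fid_rows = {arm: {"rmse": [], "ssim": []} for arm in ("ctless", "nac")}
        subj_ids = []
        for d in diags:
            subj_ids.append(d["subject_id"])
            for arm in ("ctless", "nac"):
                r, s = d["fidelity"][arm]
                fid_rows[arm]["rmse"].append(r)
                fid_rows[arm]["ssim"].append(s)
        fid_summary = {}
        for metric, better_low in (("rmse", True), ("ssim", False)):
            a = np.asarray(fid_rows["nac"][metric], float)
            b = np.asarray(fid_rows["ctless"][metric], float)
            diffs = (a - b) if better_low else (b - a)  # positive => ctless better
            boot = bootstrap_diff(diffs, np.asarray(subj_ids), B=config.bootstrap_B,
                                  seed=config.seed + 9, alpha=config.alpha)
            fid_summary[metric] = {
                "ctless_mean": float(b.mean()), "nac_mean": float(a.mean()),
                "ctless_better_diff": boot,
            }

        report = {
            "config": asdict(config),
            "n_samples": int(len(manifest)),
            "n_present": int((labels == 1).sum()),
            "n_absent": int((labels == 0).sum()),
            "arms": {arm: {"auc": aucs[arm].auc, "variance": aucs[arm].variance,
                           "ci": list(aucs[arm].ci)} for arm in ARMS},
            "comparisons": comparisons,
            "stratified_auc": strat,
            "fidelity": fid_summary,
            "segmentation": {
                "mean_dice_muscles": float(np.mean([d["dice_muscles"] for d in diags])),
                "mean_dice_lungs": float(np.mean([d["dice_lungs"] for d in diags])),
                "mu_rmse_ctless": [d["mu_rmse_ctless"] for d in diags],
                "mu_rmse_zero": [d["mu_rmse_zero"] for d in diags],
            },
            "runtime_s": time.time() - t0,
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
        raise RuntimeError(f"study failed in stage '{stage}': {exc}") from exc

    if out_dir is not None:
        _write_report(report, manifest, features, scores, out_dir)
    return report


def _write_report(report, manifest, features, scores, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    df = manifest.copy()
    for arm in ARMS:
        for c in range(features[arm].shape[1]):
            df[f"{arm}_v{c + 1}"] = features[arm][:, c]
        df[f"{arm}_t"] = scores[arm]
    df.to_csv(out / "scores.csv", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        labels = manifest.label.to_numpy()
        for arm in ARMS:
            r = roc_auc(scores[arm], labels)
            ax.plot(r.fpr, r.tpr, label=f"{arm} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "roc.png", dpi=120)
        plt.close(fig)
    except ImportError:
        log.info("matplotlib unavailable; skipping ROC plot")
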