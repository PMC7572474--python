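"""GC-MS style metabolomics QC: blank-based contaminant removal, pool-based
prevalence filtering, instrument-drift normalization, and intracellular /
extracellular ratio computation.

A run couples a metabolite × measurement intensity matrix with an ordered
manifest labelling each measurement as sample, pool (a mixture of all
extracts, injected after every fifth measurement) or blank.  Detection means
present and > 0.  Missing intensities are treated as 0 in blank/sample means
(conservative contaminant removal; a detected-only alternative is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("nichescope")


@dataclass
class MetaboliteRun:
    """Intensity matrix plus measurement-sequence manifest for one fraction."""

    intensities: pd.DataFrame  # metabolite × measurement_id, NaN = not detected
    manifest: pd.DataFrame  # measurement_id, position, role, sample_id
    fraction: str = ""

    def __post_init__(self) -> None:
        roles = set(self.manifest["role"])
        if not roles <= {"sample", "pool", "blank"}:
            raise ValueError(f"unknown roles {roles - {'sample', 'pool', 'blank'}}")
        order = self.manifest.sort_values("position")["measurement_id"]
        self.manifest = self.manifest.sort_values("position").reset_index(drop=True)
        self.intensities = self.intensities[list(order)]

    def columns_of(self, role: str) -> list[str]:
        return list(self.manifest.loc[self.manifest["role"] == role, "measurement_id"])


def blank_filter(
    run: MetaboliteRun, threshold: float = 0.75, detected_only: bool = False
) -> tuple[MetaboliteRun, list[str]]:
    """Remove contaminants: metabolites whose mean blank intensity exceeds
    75% of their mean sample intensity (strictly greater).

    Means are over all measurements of each role with missing treated as 0;
    ``detected_only=True`` switches to means over detected values only.
    Without blanks the run passes through with a warning.
    """
    blanks = run.columns_of("blank")
    samples = run.columns_of("sample")
    if not samples:
        raise ValueError("run has no sample measurements")
    if not blanks:
        log.warning("no blank measurements: blank filter is a pass-through")
        return run, []
    inten = run.intensities
    if detected_only:
        mean_blank = inten[blanks].where(inten[blanks] > 0).mean(axis=1).fillna(0.0)
        mean_sample = inten[samples].where(inten[samples] > 0).mean(axis=1).fillna(0.0)
    else:
        mean_blank = inten[blanks].fillna(0.0).mean(axis=1)
        mean_sample = inten[samples].fillna(0.0).mean(axis=1)
    removed = list(inten.index[mean_blank > threshold * mean_sample])
    kept = MetaboliteRun(
        intensities=inten.drop(index=removed),
        manifest=run.manifest,
        fraction=run.fraction,
    )
    return kept, removed


def prevalence_filter(
    run: MetaboliteRun,
    min_sample_frac: float = 0.25,
    require_all_pools: bool = True,
) -> MetaboliteRun:
    """Keep metabolites detected in every pool and in ≥ ``min_sample_frac``
    of sample measurements (0.90 for correlation workflows)."""
    pools = run.columns_of("pool")
    samples = run.columns_of("sample")
    inten = run.intensities
    detected = inten.fillna(0.0) > 0
    keep = detected[samples].mean(axis=1) >= min_sample_frac
    if require_all_pools and pools:
        keep &= detected[pools].all(axis=1)
    return MetaboliteRun(
        intensities=inten.loc[keep], manifest=run.manifest, fraction=run.fraction
    )


def drift_normalize(run: MetaboliteRun) -> tuple[MetaboliteRun, list[str]]:
    """Normalize instrument drift against neighbouring pool injections.

    Every measurement's intensity is divided by the mean of that metabolite's
    intensities in up to two nearest preceding and up to two nearest
    following pool samples (≤ 4 pools total) in the measurement sequence.
    Pools where the metabolite is undetected are skipped; if no usable pool
    value exists, the value is left unnormalized and the metabolite flagged.
    The operation is scale-equivariant: multiplying the whole run by a
    constant leaves normalized values unchanged.
    """
    manifest = run.manifest
    pool_pos = manifest.loc[manifest["role"] == "pool", "position"].values
    if len(pool_pos) == 0:
        raise ValueError("run has no pool measurements")
    inten = run.intensities
    positions = manifest["position"].values
    cols = list(manifest["measurement_id"])
    out = inten.copy().astype(float)
    flagged: list[str] = []
    pool_cols = run.columns_of("pool")
    pool_vals = inten[pool_cols].values  # metabolite × pool, sequence order
    pool_positions = manifest.set_index("measurement_id").loc[pool_cols, "position"].values

    for mi, met in enumerate(inten.index):
        pv = pool_vals[mi]
        usable = np.isfinite(pv) & (pv > 0)
        if not usable.any():
            flagged.append(met)
            log.warning("metabolite %s absent from all pools: left unnormalized", met)
            continue
        upos = pool_positions[usable]
        uval = pv[usable]
        for ci, col in enumerate(cols):
            p = positions[ci]
            val = out.iat[mi, ci]
            if not np.isfinite(val):
                continue
            before = np.where(upos < p)[0]
            after = np.where(upos > p)[0]
            chosen = list(before[-2:]) + list(after[:2])
            if not chosen:
                # measurement is itself the only pool, or no flanking pools
                chosen = list(np.where(upos == p)[0])
            if not chosen:
                continue
            out.iat[mi, ci] = val / uval[chosen].mean()
    return MetaboliteRun(intensities=out, manifest=manifest, fraction=run.fraction), flagged


def pool_drift_qc(raw: MetaboliteRun, normalized: MetaboliteRun) -> pd.DataFrame:
    """Drift-removal QC over pool injections with complete windows.

    Pools are the only replicated material in the run, so they carry the
    drift signal without biological variance.  Boundary pools lack the full
    two-preceding/two-following window and are excluded from the metric;
    for each metabolite detected in every interior pool the table reports
    the Spearman correlation of intensity with run position (raw and
    normalized) and the coefficient of variation across those pools (raw
    and normalized).  Effective normalization drives |rho_norm| toward 0
    and cv_norm below cv_raw.
    """
    from scipy.stats import spearmanr

    pools = raw.columns_of("pool")
    if len(pools) < 5:
        raise ValueError("need at least five pools for drift QC")
    interior = pools[2:-2]
    pos = raw.manifest.set_index("measurement_id").loc[interior, "position"].values
    rows = []
    for m in raw.intensities.index:
        rv = raw.intensities.loc[m, interior].values.astype(float)
        nv = normalized.intensities.loc[m, interior].values.astype(float)
        if not (np.isfinite(rv).all() and (rv > 0).all()):
            continue
        rows.append(
            {
                "metabolite_id": m,
                "rho_raw": spearmanr(pos, rv)[0],
                "rho_norm": spearmanr(pos, nv)[0],
                "cv_raw": rv.std(ddof=1) / rv.mean(),
                "cv_norm": nv.std(ddof=1) / nv.mean(),
            }
        )
    return pd.DataFrame(rows)


def intra_extra_ratio(
    intra: MetaboliteRun, extra: MetaboliteRun
) -> tuple[pd.DataFrame, list[str]]:
    """Intracellular / extracellular normalized intensity per time-point.

    Only metabolites detected in both fractions are eligible; a missing or
    zero extracellular value leaves that cell missing.  Measurements are
    matched through the manifests' sample_id links.
    """
    shared = [m for m in intra.intensities.index if m in set(extra.intensities.index)]
    in_map = intra.manifest[intra.manifest["role"] == "sample"].set_index("sample_id")[
        "measurement_id"
    ]
    ex_map = extra.manifest[extra.manifest["role"] == "sample"].set_index("sample_id")[
        "measurement_id"
    ]
    common_samples = [s for s in in_map.index if s in set(ex_map.index)]
    iv = intra.intensities.loc[shared, [in_map[s] for s in common_samples]].values
    ev = extra.intensities.loc[shared, [ex_map[s] for s in common_samples]].values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.isfinite(ev) & (ev > 0) & np.isfinite(iv), iv / ev, np.nan)
    table = pd.DataFrame(
        ratio, index=pd.Index(shared, name="metabolite_id"), columns=common_samples
    )
    return table, shared
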