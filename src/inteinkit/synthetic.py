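"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in the package has a matching generator here so that
parameter recovery can be verified end to end: gel-densitometry time
courses from the three-state splicing model, biphasic BLI sensorgrams from
the two-step binding model, bimodal SEC chromatograms, and thermal-shift
melt curves with the post-peak quench artefact.  Each generator returns
``(data, truth)`` where ``truth`` is a JSON-serialisable record of every
parameter used; identical arguments and seed give identical output.

Default conditions mirror the experimental layouts the analyses were
designed for: a seven-step two-fold BLI dilution series from 200 nM with
500 s association and dissociation phases, gel sampling with n = 3
replicate lanes and 5% multiplicative (log-normal) densitometry noise,
additive BLI noise of 0.5% of the maximal response, and melt curves on a
10-90 degC grid in 1 degC steps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bli import Sensorgram, two_step_response
from .pts import TimeCourse, three_state_profiles
from .sec import Chromatogram
from .stability import MeltCurve

__all__ = ["generate_pts_gel", "gel_table_to_timecourse",
           "generate_sensorgrams", "generate_chromatogram",
           "generate_melt_curve", "BLI_DILUTION_SERIES_M"]

#: the standard 2-fold dilution series, 200 down to 3.125 nM, in molar
BLI_DILUTION_SERIES_M = tuple(200e-9 / 2 ** i for i in range(7))

DEFAULT_MASSES = {"A": 58.2, "BI": 74.8, "P": 70.1}  # kDa


def _lognormal_factor(rng, sd, size):
    """Multiplicative noise with unit mean and relative s.d. ~ sd."""
    if sd == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(sd ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def generate_pts_gel(k1, k2, k3, times, active_fraction=0.3,
                     masses=None, gain=1.0, noise_sd=0.05,
                     n_replicates=3, include_inactive_band=False,
                     scheme="three_state", k_total=None, seed=0):
    """Synthetic densitometry table for a splicing time course.

    With the default ``scheme="three_state"``, species amounts follow the
    three-state closed form with ``P_max = active_fraction`` (the
    splice-incompetent precursor fraction is aggregated and, by default,
    not part of the resolved precursor band; set
    ``include_inactive_band=True`` to add it as a constant offset on A).
    With ``scheme="single_exponential"`` the product trace is the
    pseudo-first-order form P(t) = P_max (1 - exp(-k_total t)) and A its
    complement (no BI band).  Band intensity = moles x mass x gain,
    perturbed by multiplicative log-normal noise per band.

    Returns
    -------
    (pandas.DataFrame, dict)
        Long table (time_s, species, intensity, replicate) and the truth
        record.
    """
    rng = np.random.default_rng(seed)
    masses = dict(masses or DEFAULT_MASSES)
    times = np.asarray(times, dtype=float)
    if scheme == "three_state":
        prof = three_state_profiles(k1, k2, k3, active_fraction, times)
        if include_inactive_band:
            prof = dict(prof)
            prof["A"] = prof["A"] + (1.0 - active_fraction)
    elif scheme == "single_exponential":
        kt = k3 if k_total is None else k_total
        p = active_fraction * (1.0 - np.exp(-kt * times))
        prof = {"A": active_fraction - p, "P": p}
        if include_inactive_band:
            prof["A"] = prof["A"] + (1.0 - active_fraction)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rows = []
    for rep in range(n_replicates):
        for species, moles in prof.items():
            intensity = moles * masses[species] * gain
            intensity = intensity * _lognormal_factor(rng, noise_sd,
                                                      len(times))
            for t, inten in zip(times, intensity):
                rows.append((t, species, inten, rep))
    table = pd.DataFrame(rows, columns=["time_s", "species", "intensity",
                                        "replicate"])
    truth = {"k1": k1, "k2": k2, "k3": k3, "scheme": scheme,
             "k_total": (k3 if k_total is None else k_total)
             if scheme == "single_exponential" else None,
             "active_fraction": active_fraction, "masses": masses,
             "gain": gain, "noise_sd": noise_sd,
             "n_replicates": n_replicates,
             "include_inactive_band": include_inactive_band, "seed": seed}
    return table, truth


def gel_table_to_timecourse(table: pd.DataFrame, masses=None) -> TimeCourse:
    """Average replicate lanes and build a :class:`TimeCourse`."""
    mean = (table.groupby(["time_s", "species"], sort=True)["intensity"]
            .mean().reset_index())
    return TimeCourse.from_dataframe(mean, masses=dict(masses or DEFAULT_MASSES))


def generate_sensorgrams(ka, kd, kf, ku, concentrations=BLI_DILUTION_SERIES_M,
                         t_assoc=500.0, t_dissoc=500.0, dt=1.0, c0=1.0,
                         alpha=1.0, beta=1.0, noise_sd=0.005, seed=0):
    """Synthetic biphasic sensorgrams over a concentration series.

    Each trace is the closed-form two-step response Y = alpha*[N.C] +
    beta*[NC] with additive Gaussian noise of ``noise_sd`` times that
    trace's own maximal response (instrument noise scales with the signal
    level of the channel).  ``c0`` sets the sensor ligand amount (response
    units are proportional to it).
    """
    rng = np.random.default_rng(seed)
    ta = np.arange(0.0, t_assoc + dt / 2, dt)
    td = np.arange(dt, t_dissoc + dt / 2, dt)
    traces = []
    for c in concentrations:
        ya, yd = two_step_response(ka, kd, kf, ku, c, ta, td, c0=c0,
                                   alpha=alpha, beta=beta)
        times = np.concatenate([ta, t_assoc + td])
        resp = np.concatenate([ya, yd])
        resp = resp + rng.normal(0.0, noise_sd * ya.max(), size=resp.shape)
        traces.append(Sensorgram(times=times, response=resp, conc=float(c),
                                 t_assoc_start=0.0, t_dissoc_start=t_assoc))
    truth = {"ka": ka, "kd": kd, "kf": kf, "ku": ku,
             "concentrations_M": list(map(float, concentrations)),
             "t_assoc_s": t_assoc, "t_dissoc_s": t_dissoc, "dt_s": dt,
             "c0": c0, "alpha": alpha, "beta": beta, "noise_sd": noise_sd,
             "seed": seed}
    return traces, truth


def generate_chromatogram(peaks, v0=8.0, vt=24.0, n_points=600,
                          baseline=0.0, noise_sd=0.0, shape="gaussian",
                          tau=0.3, seed=0):
    """Synthetic SEC trace from (center_mL, width_mL, area) peak tuples.

    Peak shape is Gaussian by default; ``shape="emg"`` gives an
    exponentially modified Gaussian with tailing constant ``tau`` (mL).
    Additive Gaussian noise is scaled to the maximal peak height.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    # leave flat margin either side so baseline estimation sees true baseline
    v = np.linspace(v0 - 2.5, vt + 1.0, n_points)
    a = np.full_like(v, float(baseline))
    for center, width, area in peaks:
        if width <= 0:
            raise ValueError(f"peak at {center} mL has non-positive width")
        if shape == "gaussian":
            a = a + area * stats.norm.pdf(v, loc=center, scale=width)
        elif shape == "emg":
            a = a + area * stats.exponnorm.pdf(v, K=tau / width, loc=center,
                                               scale=width)
        else:
            raise ValueError(f"unknown peak shape {shape!r}")
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd * a.max(), size=a.shape)
    chrom = Chromatogram(volumes=v, absorbance=a, v0=v0, vt=vt)
    truth = {"peaks": [list(map(float, p)) for p in peaks], "v0": v0,
             "vt": vt, "baseline": baseline, "noise_sd": noise_sd,
             "shape": shape, "seed": seed}
    return chrom, truth


def generate_melt_curve(t_m=61.4, b=0.25, y_min=0.05, y_max=1.0,
                        quench_onset=None, quench_slope=0.03,
                        t_grid=None, noise_sd=0.01, n_replicates=1,
                        seed=0):
    """Synthetic thermal-shift curve: logistic transition plus quench.

    The underlying signal is the four-parameter logistic; past
    ``quench_onset`` (degC) a linear decay of ``quench_slope`` per degC
    emulates the aggregation-quench of the dye signal.  Additive Gaussian
    noise of ``noise_sd`` x (y_max - y_min).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(10.0, 91.0, 1.0) if t_grid is None else np.asarray(
        t_grid, dtype=float)
    base = y_min + (y_max - y_min) / (1.0 + 10.0 ** ((t_m - t) * b))
    if quench_onset is not None:
        decay = np.clip(t - quench_onset, 0.0, None) * quench_slope
        base = base - decay * (y_max - y_min)
    temps, fluos, reps = [], [], []
    for rep in range(n_replicates):
        noisy = base + rng.normal(0.0, noise_sd * (y_max - y_min),
                                  size=base.shape)
        temps.append(t)
        fluos.append(noisy)
        reps.append(np.full(t.shape, rep))
    curve = MeltCurve(temperature=np.concatenate(temps),
                      fluorescence=np.concatenate(fluos),
                      replicate=np.concatenate(reps))
    truth = {"T_M": t_m, "b": b, "Ymin": y_min, "Ymax": y_max,
             "quench_onset": quench_onset, "quench_slope": quench_slope,
             "noise_sd": noise_sd, "n_replicates": n_replicates,
             "seed": seed}
    return curve, truth
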