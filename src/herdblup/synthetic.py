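"""Two-country synthetic herdbook generator.

Emulates the data structure the evaluation model assumes: per country, a founder
population of AI sires and dams, one recorded daughter generation assigned to
herds and herd-year-season cells, and first-lactation phenotypes

    y = country mean + herd + HYS + age·slope (except AFC) + TBV + e

with true breeding values drawn from the trait×trait genetic covariance G0
(founders) or parent-average plus Mendelian sampling (daughters), and residuals
from R0 with configurable per-trait missingness.  A configurable subset of sires
is shared between the countries and is the only genetic link across them —
connectedness is sire-only, mirroring semen exchange rather than shared cow
families.

Sire usage is skewed by default (geometric-like daughter counts, heavy use of a
few popular AI bulls) with every sire guaranteed at least one recorded daughter,
so the configured sire counts are exactly the counts of sires *with daughter
records*.
"""

from __future__ import annotations

import datetime as _dt
import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, DEFAULT_COUNTRY_MEANS, TRAITS
from .hys import make_hys

__all__ = ["SimOutput", "simulate_study", "truth_diagnostics"]


@dataclass
class SimOutput:
    cfg: SimConfig
    pedigree: dict[str, pd.DataFrame]      # country -> animal_id,sire_id,dam_id
    performance: dict[str, pd.DataFrame]   # country -> performance CSV dialect
    shared_sires: list[str]
    truth: pd.DataFrame                    # long: country,animal_id,trait,tbv
    truth_fixed: dict                      # herd/hys/country-mean/age-slope truth
    residuals: pd.DataFrame                # long: country,animal_id,trait,resid

    def write(self, outdir) -> dict:
        """Write pedigree/performance CSVs, truth.tsv, shared-sire list, manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        for name in self.pedigree:
            p = outdir / f"{name.lower()}_pedigree.csv"
            self.pedigree[name].to_csv(p, index=False)
            files[f"pedigree_{name}"] = p.name
            q = outdir / f"{name.lower()}_performance.csv"
            self.performance[name].to_csv(q, index=False)
            files[f"performance_{name}"] = q.name
        tpath = outdir / "truth.tsv"
        self.truth.to_csv(tpath, sep="\t", index=False)
        files["truth"] = tpath.name
        spath = outdir / "shared_sires.txt"
        spath.write_text("\n".join(self.shared_sires) + ("\n" if self.shared_sires else ""))
        files["shared_sires"] = spath.name
        manifest = {
            "seed": self.cfg.seed,
            "files": files,
            "checksums": {k: _sha256(outdir / v) for k, v in files.items()},
            "truth_parameters": {
                "sigma_g": np.sqrt(np.diag(self.cfg.varcomp.G0)).tolist(),
                "heritabilities": self.cfg.varcomp.heritabilities().tolist(),
                "note": "truth G0/R0, fixed-effect SDs and country means are "
                        "simulator assumptions, not estimates from any real herdbook",
            },
        }
        (outdir / "sim_manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _daughter_counts(rng: np.random.Generator, n_sires: int, n_cows: int,
                     usage: str) -> np.ndarray:
    """Daughters per sire: minimum one each, remainder multinomial.

    Geometric-like weights emulate heavy use of popular AI bulls; sire popularity
    order is randomized so shared sires are not systematically the most used.
    """
    if n_cows < n_sires:
        raise ValueError(f"need at least one cow per sire ({n_cows} < {n_sires})")
    counts = np.ones(n_sires, dtype=np.int64)
    rest = n_cows - n_sires
    if rest > 0:
        if usage == "uniform":
            w = np.ones(n_sires)
        else:
            decay = 1.0 - 3.0 / n_sires if n_sires > 3 else 0.5
            w = decay ** np.arange(n_sires)
            rng.shuffle(w)
        counts += rng.multinomial(rest, w / w.sum())
    return counts


def simulate_study(cfg: SimConfig, outdir=None) -> SimOutput:
    """Generate the two-country herdbook defined by ``cfg``.

    Deterministic for a fixed config (seeded); writes the external-interface files
    when ``outdir`` is given.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vc = cfg.varcomp
    t = len(TRAITS)
    g_chol = np.linalg.cholesky(vc.G0)
    r_chol = np.linalg.cholesky(vc.R0)

    shared = [f"CS{i + 1:03d}" for i in range(cfg.n_common_sires)]
    shared_tbv = (g_chol @ rng.standard_normal((t, len(shared)))).T

    pedigree: dict[str, pd.DataFrame] = {}
    performance: dict[str, pd.DataFrame] = {}
    truth_rows: list[tuple] = []
    resid_rows: list[tuple] = []
    truth_fixed: dict = {"country_mean": {}, "herd": {}, "hys": {},
                         "age_slope": dict(cfg.age_slope)}

    for country in cfg.countries:
        name = country.name
        n_local = country.n_sires - cfg.n_common_sires
        sires = shared + [f"S{i + 1:04d}" for i in range(n_local)]
        dams = [f"D{i + 1:05d}" for i in range(country.n_dams)]
        cows = [f"C{i + 1:05d}" for i in range(country.n_cows)]

        sire_tbv = np.vstack([
            shared_tbv,
            (g_chol @ rng.standard_normal((t, n_local))).T,
        ]) if country.n_sires else np.zeros((0, t))
        dam_tbv = (g_chol @ rng.standard_normal((t, country.n_dams))).T

        counts = _daughter_counts(rng, country.n_sires, country.n_cows, cfg.sire_usage)
        cow_sire = np.repeat(np.arange(country.n_sires), counts)
        rng.shuffle(cow_sire)
        cow_dam = rng.integers(0, country.n_dams, size=country.n_cows)
        # founder parents are non-inbred, so the Mendelian-sampling covariance is G0/2
        mend = (g_chol @ rng.standard_normal((t, country.n_cows))).T * np.sqrt(0.5)
        cow_tbv = 0.5 * (sire_tbv[cow_sire] + dam_tbv[cow_dam]) + mend

        ped = pd.DataFrame({
            "animal_id": sires + dams + cows,
            "sire_id": ["0"] * (country.n_sires + country.n_dams)
                       + [sires[s] for s in cow_sire],
            "dam_id": ["0"] * (country.n_sires + country.n_dams)
                      + [dams[d] for d in cow_dam],
        })
        pedigree[name] = ped

        herds = [f"H{i + 1:03d}" for i in range(country.n_herds)]
        cow_herd = rng.integers(0, country.n_herds, size=country.n_cows)
        years = rng.integers(country.year_start, country.year_end + 1,
                             size=country.n_cows)
        doy = rng.integers(0, 365, size=country.n_cows)
        dates = [
            (_dt.date(int(y), 1, 1) + _dt.timedelta(days=int(d))).isoformat()
            for y, d in zip(years, doy)
        ]
        age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=country.n_cows),
                      20.0, None)

        means = cfg.country_mean.get(name) or DEFAULT_COUNTRY_MEANS.get(
            name, {tr: 0.0 for tr in TRAITS})
        herd_eff = {tr: rng.normal(0.0, cfg.herd_sd[tr], size=country.n_herds)
                    for tr in TRAITS}
        hys_labels = [make_hys(herds[h], d, cfg.season_rule)
                      for h, d in zip(cow_herd, dates)]
        cells = sorted(set(hys_labels))
        cell_idx = {c: i for i, c in enumerate(cells)}
        hys_eff = {tr: rng.normal(0.0, cfg.hys_sd[tr], size=len(cells))
                   for tr in TRAITS}

        resid = (r_chol @ rng.standard_normal((t, country.n_cows))).T
        pheno = np.empty((country.n_cows, t))
        for j, tr in enumerate(TRAITS):
            slope = cfg.age_slope[tr] if tr != "afc" else 0.0
            pheno[:, j] = (
                means[tr]
                + herd_eff[tr][cow_herd]
                + hys_eff[tr][[cell_idx[c] for c in hys_labels]]
                + slope * (age - cfg.age_mean)
                + cow_tbv[:, j]
                + resid[:, j]
            )

        miss = np.zeros((country.n_cows, t), dtype=bool)
        for j, tr in enumerate(TRAITS):
            rate = cfg.missing_rates.get(tr, 0.0)
            if rate > 0:
                miss[:, j] = rng.random(country.n_cows) < rate
        all_missing = miss.all(axis=1)
        miss[all_missing, 0] = False  # every record keeps at least one trait

        perf = pd.DataFrame({
            "animal_id": cows,
            "country": name,
            "herd": [herds[h] for h in cow_herd],
            "calving_date": dates,
            "age_months": np.round(age, 2),
        })
        for j, tr in enumerate(TRAITS):
            col = np.round(pheno[:, j], 4).astype(object)
            col[miss[:, j]] = ""
            perf[tr] = col
        performance[name] = perf

        tbv_all = np.vstack([sire_tbv, dam_tbv, cow_tbv])
        ids_all = sires + dams + cows
        for i, a in enumerate(ids_all):
            for j, tr in enumerate(TRAITS):
                truth_rows.append((name, a, tr, tbv_all[i, j]))
        for i, a in enumerate(cows):
            for j, tr in enumerate(TRAITS):
                resid_rows.append((name, a, tr, resid[i, j]))
        truth_fixed["country_mean"][name] = dict(means)
        truth_fixed["herd"][name] = {h: {tr: herd_eff[tr][i] for tr in TRAITS}
                                     for i, h in enumerate(herds)}
        truth_fixed["hys"][name] = {c: {tr: hys_eff[tr][cell_idx[c]] for tr in TRAITS}
                                    for c in cells}

    out = SimOutput(
        cfg=cfg,
        pedigree=pedigree,
        performance=performance,
        shared_sires=shared,
        truth=pd.DataFrame(truth_rows,
                           columns=["country", "animal_id", "trait", "tbv"]),
        truth_fixed=truth_fixed,
        residuals=pd.DataFrame(resid_rows,
                               columns=["country", "animal_id", "trait", "resid"]),
    )
    if outdir is not None:
        out.write(outdir)
    return out


def truth_diagnostics(sim: SimOutput) -> dict:
    """Realized moments of the simulated truth.

    Reports the realized founder TBV covariance, the realized per-trait variance
    decomposition among recorded cows (TBV variance over TBV+residual variance,
    the simulator's operational heritability), and connectedness counts.
    """
    cfg = sim.cfg
    founders: dict[str, np.ndarray] = {}
    real_h2 = {}
    tbv_wide = sim.truth.pivot_table(index=["country", "animal_id"], columns="trait",
                                     values="tbv")[TRAITS]
    res_wide = sim.residuals.pivot_table(index=["country", "animal_id"],
                                         columns="trait", values="resid")[TRAITS]

    founder_rows = []
    for country in cfg.countries:
        ped = sim.pedigree[country.name]
        f_ids = ped.loc[(ped["sire_id"] == "0") & (ped["dam_id"] == "0"), "animal_id"]
        founder_rows.append(tbv_wide.loc[country.name].loc[f_ids].to_numpy())
    founder_tbv = np.vstack(founder_rows)
    founders["realized_G0"] = np.cov(founder_tbv.T)

    cow_idx = res_wide.index
    cow_tbv = tbv_wide.loc[cow_idx].to_numpy()
    cow_res = res_wide.to_numpy()
    for j, tr in enumerate(TRAITS):
        vg = np.var(cow_tbv[:, j], ddof=1)
        ve = np.var(cow_res[:, j], ddof=1)
        real_h2[tr] = vg / (vg + ve)

    # only the declared shared sires denote the same animal across countries;
    # other ids are country-local and may collide textually
    sire_sets = {
        c.name: set(sim.performance[c.name]["animal_id"].map(
            dict(zip(sim.pedigree[c.name]["animal_id"],
                     sim.pedigree[c.name]["sire_id"]))))
        for c in cfg.countries
    }
    common = set(sim.shared_sires)
    for s in sire_sets.values():
        common &= s
    return {
        "realized_G0": founders["realized_G0"],
        "configured_G0": cfg.varcomp.G0,
        "realized_h2": real_h2,
        "configured_h2": {tr: h for tr, h in zip(TRAITS, cfg.varcomp.heritabilities())},
        "n_founders": founder_tbv.shape[0],
        "common_sires_with_daughters": len(common),
    }
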