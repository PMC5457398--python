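"""Shared test utilities: trace builders and independent oracles."""

from __future__ import annotations

import base64
import math

import numpy as np

from srmtdm.assay import build_cetuximab_assay
from srmtdm.chromatogram import Chromatogram


def gaussian_trace(
    amplitude=1000.0,
    center=8.8,
    sigma=0.05,
    baseline=0.0,
    t0=8.3,
    t1=9.3,
    dt=0.005,
    extra_peaks=(),
    transition=None,
    sample_id="t",
):
    """A synthetic trace: flat baseline + one or more Gaussian peaks."""
    if transition is None:
        transition = build_cetuximab_assay()[0].quantifier("light")
    times = np.arange(t0, t1 + dt / 2, dt)
    y = np.full_like(times, float(baseline))
    for amp, c, s in ((amplitude, center, sigma),) + tuple(extra_peaks):
        y = y + amp * np.exp(-0.5 * ((times - c) / s) ** 2)
    return Chromatogram(sample_id, transition, times, y)


def fisher_p_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive fixed-margin enumeration.

    Exact integer hypergeometric numerators, so probability ties are
    decided exactly; independent of any library implementation.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r, col = a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    probs = {
        k: math.comb(r, k) * math.comb(n - r, col - k) for k in range(lo, hi + 1)
    }
    pobs = probs[a]
    return sum(v for v in probs.values() if v <= pobs) / math.comb(n, col)


def conditional_mle_or_oracle(table) -> float:
    """Conditional-MLE odds ratio by direct likelihood maximization.

    Maximizes the noncentral hypergeometric likelihood of the observed
    cell over the odds-ratio parameter (log-scale grid + golden refine).
    """
    from scipy.optimize import minimize_scalar

    (a, b), (c, d) = table
    n, r, col = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    ks = np.arange(lo, hi + 1)
    logw = np.array(
        [math.lgamma(r + 1) - math.lgamma(k + 1) - math.lgamma(r - k + 1)
         + math.lgamma(n - r + 1) - math.lgamma(col - k + 1)
         - math.lgamma(n - r - col + k + 1) for k in ks]
    )

    def neg_loglik(logpsi):
        terms = logw + ks * logpsi
        m = terms.max()
        return -(logw[a - lo] + a * logpsi - (m + np.log(np.exp(terms - m).sum())))

    if a == lo:
        return 0.0
    if a == hi:
        return math.inf
    res = minimize_scalar(neg_loglik, bounds=(-30, 30), method="bounded",
                          options={"xatol": 1e-12})
    return float(np.exp(res.x))


def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def write_synthetic_mzml(path, traces) -> None:
    """Write a minimal synthetic mzML chromatogram list for reader tests.

    ``traces``: iterable of (precursor_mz, product_mz, times_min, intensities).
    """
    chroms = []
    for i, (prec, prod, times, intens) in enumerate(traces):
        t64, i64 = _b64(times), _b64(intens)
        chroms.append(f"""
    <chromatogram index="{i}" id="SRM SIC Q1={prec} Q3={prod}" defaultArrayLength="{len(times)}">
      <precursor><isolationWindow>
        <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{prec}"/>
      </isolationWindow></precursor>
      <product><isolationWindow>
        <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{prod}"/>
      </isolationWindow></product>
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="{len(t64)}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000595" name="time array" value="" unitName="minute"/>
          <binary>{t64}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="{len(i64)}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{i64}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </chromatogram>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="synthetic">
    <chromatogramList count="{len(chroms)}">{''.join(chroms)}
    </chromatogramList>
  </run>
</mzML>
"""
    with open(path, "w") as fh:
        fh.write(doc)
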