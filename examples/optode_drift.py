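"""Quantify optode placement drift between the two digitized sessions.

Computes per-optode Euclidean shifts (Session 1 -> Session 2), per-optode
cross-subject composite SDs, and the association between channel-midpoint
drift and the across-session change in channel beta estimates.
"""

from spafnirs.pipeline import RunConfig, run_study

res = run_study(RunConfig(seed=0))
s = res.shift_summary

print(f"grand mean optode shift: {s.grand_mean_mm:.3f} mm "
      f"(SD {s.grand_sd_mm:.3f} mm) over {len(s.shifts)} subject x optode pairs")
print(f"mean of per-optode means: {s.grand_mean_of_optode_means_mm:.3f} mm")

worst = s.per_optode.sort_values("mean_shift_mm").iloc[-1]
print(f"largest per-optode mean shift: {worst['optode']} at "
      f"{worst['mean_shift_mm']:.3f} mm (SD {worst['sd_shift_mm']:.3f})")

d = s.dispersion
w = d.loc[d["composite_sd_mm"].idxmax()]
print(f"largest positional dispersion: {w['optode']} session {w['session']:.0f}, "
      f"composite SD {w['composite_sd_mm']:.3f} mm")

r, p = res.association
print(f"\nchannel shift vs |delta beta| (ss_tcca): r = {r:.3f}, p = {p:.3f}")
print("Shifts are on the ~1 cm scale of cap re-placement. Shift and beta "
      "change are independent in the generator, so r is zero on average; "
      "a single 11-subject study pools clustered channels, though, so "
      "individual estimates scatter widely around zero (the nominal p is "
      "anti-conservative under that clustering).")
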