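"""Dose-response of the total score to a global impairment level.

Sweeps the generator's global deficit from none (1.0) to complete (0.0) and
prints the resulting totals and severity classes — the total must never
increase as impairment deepens.
"""

from fmaue import ImpairmentProfile, assess, gen_recording

print("impairment  total  severity")
for level in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0):
    profile = ImpairmentProfile(
        rom_scale=level, velocity_scale=level, force_scale=level, seed=1
    )
    report = assess(gen_recording(profile))
    print(f"   {level:4.1f}     {report.total:>3}    {report.severity}")
print()
print("Levels on the membership plateaus (1.0 / 0.5 / 0.0) score exactly")
print("60 / 30 / 0. Because a uniform deficit gives every item the same")
print("feature ratios, items cross their score boundaries together and the")
print("total steps down in plateaus; it never increases as deficit deepens.")
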