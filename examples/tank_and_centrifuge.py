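"""Size the de-foaming tank and select the centrifuge for one scenario."""
from wheyfrac import select_centrifuge_g, tank_spec

spec = tank_spec(W_liq=907, P=8.3)
print(f"foam regime at 8.3 MPa: {spec.regime}")
print(f"minimum de-foaming tank volume: {spec.V_tank:.1f} L")
print(f"liquid residence time: {spec.t_s:.1f} min")
# At 0.1 kg/L foam density and 0.4 /min drainage, 907 kg/h of foam needs a
# ~378 L tank; the liquid spends 25 min in it while the foam drains.

print(f"\nregime at 31 MPa: {tank_spec(907, 31.0).regime} — the foam breaks "
      "during extraction (a tank is still installed in the plant design)")

for C in (5, 10):
    print(f"centrifuge for {C} wt% feed: {select_centrifuge_g(C):,.0f} g")
# Solid compaction plateaus by ~10,000 g for 5-10 wt% feeds; above 10 wt%
# no plateau was observed, so selection raises an error there.
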