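"""Search for the critical landing height at which cartilage damage
initiates, using the 20/10/5/1-cm refinement schedule.

Every input is synthetic and seeded; the contact model is an elastic
foundation, so the critical height is a property of the surrogate
configuration, not a patient prediction.
"""

from kneeland import pipeline as pl

cfg = pl.PipelineConfig()
print(f"start {cfg.start_height_cm:.0f} cm, schedule {cfg.schedule_cm}, "
      f"damage threshold {cfg.damage_threshold}")
res = pl.critical_height_search(config=cfg)
print("search trace (height, damaged):")
for h, d in res.search_trace:
    print(f"  {h:4d} cm  {'DAMAGE' if d else 'ok'}")
print(f"critical landing height: {res.critical_height} cm "
      f"({res.n_evaluations} pipeline evaluations)")

ev = pl.evaluate_height(float(res.critical_height), cfg)
print(f"at that height: joint load {ev.joint_load_bw:.2f} BW, peak contact "
      f"pressure {ev.contact.peak_pressure_mpa:.2f} MPa, max damage "
      f"indicator {ev.tissue.max_damage:.3f}")
print("The damage indicator is 1 - exp(-(W_fl/Phi)^m); the critical height "
      "is the first integer height where it crosses the threshold at any "
      "node and depth.")
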