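"""Score simulated mating timelines with E_SI and contact metrics.

Simulates one wild-type-like male and one male from an ectopic-prodding
regime (a dopamine-deficient-like phenotype in which insertion attempts
happen away from the vulva), scores both, and shows the posture proxy ICL%.
"""

from wormmate import compute_esi, compute_icl, contact_metrics
from wormmate.simulate import TimelineSimConfig, generate_timeline

for label, p_ectopic in [("wild-type-like", 0.2), ("ectopic regime", 0.8)]:
    timeline = generate_timeline(TimelineSimConfig(p_ectopic=p_ectopic, seed=6))
    esi = compute_esi(timeline)
    cm = contact_metrics(timeline)
    print(f"{label}:")
    print(
        f"  t_prod={esi.t_prod:.1f} s, t_nonprod={esi.t_nonprod:.1f} s, "
        f"penetrated={esi.penetrated}, E_SI={esi.score:.4f}"
    )
    print(
        f"  vulva contacts={cm.n_vulva_contacts}, "
        f"total vulva contact={cm.total_vulva_contact:.1f} s"
    )

# ICL%: fraction of the male body outline touching the mate; low values
# indicate the arched posture that accompanies insertion attempts.
print(f"arched posture  ICL = {compute_icl(250.0, 1000.0):.0f}%")
print(f"relaxed posture ICL = {compute_icl(620.0, 1000.0):.0f}%")

# A male that spends its contact time prodding the vulva (and penetrates)
# scores orders of magnitude higher than one prodding ectopically.
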