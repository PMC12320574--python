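# Principal alpha emission lines of the Ac-225 decay chain at secular equilibrium.
# Yields are alphas per Ac-225 parent decay; minor lines are folded into the
# nearest principal line so that each nuclide's total alpha yield is preserved.
# The Bi-213 branch emits either a 5.875 MeV alpha directly (2.16%) or a
# 8.376 MeV alpha via the Po-213 beta branch (97.84%).
# role: "parent" lines belong to Ac-225 itself; "daughter" lines are added when
# the chain is modeled in equilibrium.
nuclide	energy_mev	yield	role
Ac-225	5.830	0.508	parent
Ac-225	5.794	0.268	parent
Ac-225	5.732	0.124	parent
Ac-225	5.637	0.100	parent
Fr-221	6.341	0.833	daughter
Fr-221	6.243	0.016	daughter
Fr-221	6.126	0.151	daughter
At-217	7.067	1.000	daughter
Bi-213	5.875	0.0216	daughter
Po-213	8.376	0.9784	daughter
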