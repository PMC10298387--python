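# Toy 20-residue helix just above its folding temperature: transient
# C-terminal crank (axial-free) vs unassisted control, replicated per arm.

target_kind = "helix"
n_residues = 20
label = "helix20"

epsilon = 6.5
temperature = 340.0
timestep = 0.02
friction = 0.5
n_steps = 120000          # 2400 ps
snapshot_interval = 6.0   # ps

steering_duration = 600.0 # ps
rotation_rate = 3.6       # degree/ps (1 turn / 100 ps; 6 turns total)
rotation_axial_free = true

q_threshold = 0.85
n_replicates = 5
master_seed = 2023
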