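# Example training configuration: early-stage stillness training.
animal_id = "m1"
experimenter = "trainer"

set_start_s = 5.0        # initial reward interval (s of stillness required)
set_max_s = 95.0         # maximum reward interval
n_periods = 2            # consecutive rewards before the interval changes
auto_delta_s = 5.0       # signed step applied to the interval
timeout_s = 2.0          # post-reward drinking window (movement ignored)
bonus_period_s = 60.0    # cumulative still time earning an extra reward
bonus_multiplier = 2.0   # bonus size, as a multiple of the normal reward
reward_duration_ms = 500 # valve-open time (reward size)
read_every_ms = 100      # sampling/recording period

[detector]
pixel_threshold = 15     # minimum per-pixel intensity change
area_fraction = 0.01     # fraction of unmasked pixels changed to flag motion

[subject]                # simulated-subject model (simulate subcommand)
move_hazard_per_s = 0.2
move_duration_s = 0.5
learning_factor = 0.95
drink_motion = true

[scene]                  # synthetic camera scene (frame rendering)
width = 64
height = 48
background = 120
noise_sd = 0.0
blob = [24, 16, 40, 32]
blob_delta = 60
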