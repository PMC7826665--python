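# One subject walking the 6 m corridor at 1.2 m/s, cadence 110.
seed = 1

[scene]
scan_rate = 15.0
range_noise_sd = 10.0
duration = 5.0

[sensor]
position = [-4000.0, 0.0]
heading = 0.0

[[walkers]]
start_position = [-2700.0, 0.0]
direction = 1
gait_speed = 1.2
cadence = 110.0
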