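link_group,topic,normalized_score,publication_count
learning|neuroplasticity,Synaptic plasticity,0.314,778
learning|neuroplasticity,Consolidation,0.231,360
learning|neuroplasticity,Long-term potentiation,0.145,340
learning|neuroplasticity,Perceptual learning,0.145,280
learning|neuroplasticity,Experience-dependent learning,0.059,150
learning|neuroplasticity,Generalization,0.038,99
learning|neuroplasticity,Experience-dependent plasticity,0.025,67
learning|neuroplasticity,Short-term plasticity,0.022,58
learning|neuroplasticity,Reinforcement learning,0.021,55
neuroplasticity|stroke recovery,Cortical activation,0.562,113
neuroplasticity|stroke recovery,Rehabilitation,0.438,86
learning|neuroplasticity|stroke recovery,Cognition,0.279,4032
learning|neuroplasticity|stroke recovery,Brain,0.141,3762
learning|neuroplasticity|stroke recovery,Stimulation,0.113,2830
learning|neuroplasticity|stroke recovery,Task-based learning,0.085,2136
learning|neuroplasticity|stroke recovery,Activity-based learning,0.073,1834
learning|neuroplasticity|stroke recovery,Motor learning,0.043,1090
learning|neuroplasticity|stroke recovery,Learning modifiers,0.041,1018
learning|neuroplasticity|stroke recovery,Skills,0.036,910
learning|neuroplasticity|stroke recovery,Movement,0.030,760
learning|neuroplasticity|stroke recovery,Impairment,0.029,732
learning|neuroplasticity|stroke recovery,Language,0.024,613
learning|neuroplasticity|stroke recovery,Connectivity,0.019,472
learning|neuroplasticity|stroke recovery,Speech,0.017,429
learning|neuroplasticity|stroke recovery,Neuroimaging,0.014,344
learning|neuroplasticity|stroke recovery,Neurorehabilitation,0.009,242
learning|neuroplasticity|stroke recovery,Motor control,0.008,203
learning|neuroplasticity|stroke recovery,BDNF,0.008,192
learning|neuroplasticity|stroke recovery,Skill learning,0.007,188
learning|neuroplasticity|stroke recovery,Functional connectivity,0.006,164
learning|neuroplasticity|stroke recovery,Brain injury,0.006,162
learning|neuroplasticity|stroke recovery,Brain activation,0.006,160
learning|neuroplasticity|stroke recovery,Sequence learning,0.004,107
learning|neuroplasticity|stroke recovery,Relearning,0.003,105
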