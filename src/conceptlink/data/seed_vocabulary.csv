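concept,term
neuroplasticity,Cells
neuroplasticity,Synapses
neuroplasticity,BDNF
neuroplasticity,Brain
neuroplasticity,Brain regions
neuroplasticity,Neuroimaging
neuroplasticity,Learning systems
neuroplasticity,White matter
neuroplasticity,Functional connectivity
neuroplasticity,Brain activation
neuroplasticity,Reorganisation
neuroplasticity,Frontal
neuroplasticity,Networks/systems
neuroplasticity,Brain network
neuroplasticity,Connection
neuroplasticity,Behavior change
neuroplasticity,Consolidation
neuroplasticity,Experience-dependent plasticity
neuroplasticity,Learning-dependent plasticity
neuroplasticity,Activity-dependent plasticity
neuroplasticity,Glial cells
neuroplasticity,Microglia
neuroplasticity,Astrocytes
neuroplasticity,Gliosis
neuroplasticity,Neuroimmunology
neuroplasticity,Blood brain barrier
neuroplasticity,Axons
neuroplasticity,Dendrites
neuroplasticity,Circulation
neuroplasticity,Neurogenesis
neuroplasticity,Progenitor cells
stroke recovery,Post-stroke
stroke recovery,Time
stroke recovery,Trajectory
stroke recovery,Function
stroke recovery,Skill
stroke recovery,Impairment
stroke recovery,Movement
stroke recovery,Sensation
stroke recovery,Language
stroke recovery,Speech
stroke recovery,Physical
stroke recovery,Cognition
stroke recovery,Mood
stroke recovery,Activity
stroke recovery,Task
stroke recovery,Work
stroke recovery,Participation
learning,Experience-dependent
learning,Experience
learning,Spontaneous
learning,Implicit
learning,Enriched environment
learning,Multisensory
learning,Multimodal
learning,Cross-modal
learning,Long-term
learning,Potentiation
learning,Environment
learning,Stimulation
learning,Performance
learning,Learning-dependent
learning,Skill learning
learning,Motor learning
learning,Perceptual learning
learning,Sensory learning
learning,Discrimination
learning,Generalisation
learning,Reinforcement learning
learning,Task-specific
learning,Sequence
learning,Errorful
learning,Errorless
learning,Challenge point
learning,Activity-dependent
learning,Adaptation
learning,Transfer
learning,"Complex, complexity"
learning,Metacognition
learning,Strategy
learning,Problem solve
learning,Generalise
learning,Novel
learning,Relearning
learning,Consolidation
learning,Well learnt
learning,Overlearn
learning,Personal experience
learning,Environment
learning,Task complexity
learning,Task switching
learning,Performance
learning,Human
learning,Individual
learning,Motivation
learning,Cognition/cognitive
learning,Concentration
learning,Transmitters
learning,Receptors
learning,Vision
learning,Hearing
learning,Perception
learning,Emotion
learning,Mood
learning,Fatigue
learning,Stress
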