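author,year,title,journal,type
Charalambous et al.,2018,The Feasibility of an Acute High-Intensity Exercise Bout to Promote Locomotor Learning after Stroke,Topics in Stroke Rehabilitation,Controlled trial
Fan et al.,2017,Transcranial Direct Current Stimulation over Multiple Days Enhances Motor Performance of a Grip Task,Annals of Physical and Rehabilitation Medicine,Controlled trial
van der Vliet et al.,2017,BDNF Val66Met but Not Transcranial Direct Current Stimulation Affects Motor Learning after Stroke,Brain Stimulation,Controlled trial
Pearson-Fuhrhop et al.,2017,Genetic Variation in the Human Brain Dopamine System Influences Motor Learning and Its Modulation by L-Dopa,PloS One,Controlled trial
Horton et al.,2017,"Adaptation, Perceptual Learning, and Plasticity of Brain Functions",Graefe's Archive for Clinical and Experimental Ophthalmology,Review
Divya et al.,2017,Post-Stroke Cognitive Impairment - A Cross-Sectional Comparison Study between Mild Cognitive Impairment of Vascular and Non-Vascular Etiology,Journal of the Neurological Sciences,Comparative study
Wadden et al.,2017,Predicting Motor Sequence Learning in Individuals with Chronic Stroke,Neurorehabilitation and Neural Repair,Controlled trial
Censor et al.,2016,Altered Human Memory Modification in the Presence of Normal Consolidation,Cerebral Cortex,Controlled trial
Siegel et al.,2016,Disruptions of Network Connectivity Predict Impairment in Multiple Behavioral Domains after Stroke,Proceedings of the National Academy of Sciences,Clinical trial
Buma et al.,2016,Brain Activation Is Related to Smoothness of Upper Limb Movements after Stroke,Experimental Brain Research,Clinical trial
Reinkensmeyer et al.,2016,Computational Neurorehabilitation: Modeling Plasticity and Learning to Predict Recovery,Journal of NeuroEngineering and Rehabilitation,Review
Soekadar et al.,2015,Brain-Machine Interfaces in Neurorehabilitation of Stroke,Neurobiology of Disease,Review
Kitago et al.,2015,Robotic Therapy for Chronic Stroke: General Recovery of Impairment or Improved Task-Specific Skill?,Journal of Neurophysiology,Clinical trial
Lefebvre et al.,2015,Neural Substrates Underlying Stimulation-Enhanced Motor Skill Learning after Stroke,Brain: A Journal of Neurology,Controlled trial
Winstein et al.,2014,Infusing Motor Learning Research into Neurorehabilitation Practice: A Historical Perspective with Case Exemplar from the Accelerated Skill Acquisition Program,Journal of Neurologic Physical Therapy: JNPT,Case study
Mang et al.,2013,Promoting Neuroplasticity for Motor Rehabilitation after Stroke: Considering the Effects of Aerobic Exercise and Genetic Variation on Brain-Derived Neurotrophic Factor,Physical Therapy,Review
Buma et al.,2013,Understanding Upper Limb Recovery after Stroke,Restorative Neurology and Neuroscience,Review
Byl et al.,2013,Effectiveness of Sensory and Motor Rehabilitation of the Upper Limb following the principles of Neuroplasticity: Patients Stable Poststroke,Neurorehabilitation and Neural Repair,Controlled trial
Bowden et al.,2013,Promoting Neuroplasticity and Recovery after Stroke: Future Directions for Rehabilitation Clinical Trials,Current Opinion in Neurology,Review
Albert and Kesselring,2012,Neurorehabilitation of Stroke,Journal of Neurology,Review
Arya et al.,2011,Movement Therapy Induced Neural Reorganization and Motor Recovery in Stroke: A Review.,Journal of Bodywork and Movement Therapies,Review
Duret,2010,[Contributions of Robotic Devices to Upper Limb Poststroke Rehabilitation],Revue Neurologique,Review
Graham et al.,2009,The Bobath Concept in Contemporary Clinical Practice,Topics in Stroke Rehabilitation,Review
Ween,2008,Functional Imaging of Stroke Recovery: An Ecological Review from a Neural Network Perspective with an Emphasis on Motor Systems,Journal of Neuroimaging,Review
Ziemann and Siebner,2008,Modifying Motor Learning through Gating and Homeostatic Metaplasticity,Brain Stimulation,Review
Daly and Ruff,2007,Construction of Efficacious Gait and Upper Limb Functional Interventions Based on Brain Plasticity Evidence and Model-Based Measures for Stroke Patients,The Scientific World Journal,Discussion paper
Hlustík and Mayer,2006,Paretic Hand in Stroke: From Motor Cortical Plasticity Research to Rehabilitation,Cognitive and Behavioral Neurology,Review
Krakauer,2006,Motor Learning: Its Relevance to Stroke Recovery and Neurorehabilitation,Current Opinion in Neurology,Review
Forrester et al.,2005,Exercise-Mediated Locomotor Recovery and Lower-Limb Neuroplasticity after Stroke,Journal of Rehabilitation Research and Development,Review
Winstein et al.,1999,Motor Learning after Unilateral Brain Damage,Neuropsychologia,Controlled trial
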