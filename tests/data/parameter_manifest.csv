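block,parameter,point,distribution,param1,param2
activity_transitions.eurofit,inactive->inactive,0.18,beta,4.0,17.0
activity_transitions.eurofit,inactive->moderate,0.054,beta,0.34,5.7
activity_transitions.eurofit,inactive->recommended,0.71,beta,59.4,19.6
activity_transitions.eurofit,moderate->inactive,0.085,beta,0.44,4.56
activity_transitions.eurofit,moderate->moderate,0.042,beta,0.09,1.9
activity_transitions.eurofit,moderate->recommended,0.82,beta,33.8,5.2
activity_transitions.eurofit,recommended->inactive,0.042,beta,0.83,18.2
activity_transitions.eurofit,recommended->moderate,0.023,beta,0.24,9.8
activity_transitions.eurofit,recommended->recommended,0.89,beta,357.9,26.1
activity_transitions.control,inactive->inactive,0.33,beta,11.5,21.5
activity_transitions.control,inactive->moderate,0.12,beta,1.6,10.4
activity_transitions.control,inactive->recommended,0.49,beta,25.0,23.0
activity_transitions.control,moderate->inactive,0.19,beta,2.1,8.0
activity_transitions.control,moderate->moderate,0.17,beta,1.5,6.6
activity_transitions.control,moderate->recommended,0.58,beta,16.6,10.4
activity_transitions.control,recommended->inactive,0.1,beta,4.2,37.8
activity_transitions.control,recommended->moderate,0.064,beta,1.9,26.1
activity_transitions.control,recommended->recommended,0.8,beta,290.7,58.3
disease_incidence,inactive->colorectal_cancer,0.015,fixed,,
disease_incidence,inactive->chd,0.011,fixed,,
disease_incidence,inactive->t2d,0.005,fixed,,
disease_incidence,inactive->stroke,0.0046,fixed,,
disease_incidence,inactive->depression,0.01,fixed,,
disease_incidence,moderate->colorectal_cancer,0.011,fixed,,
disease_incidence,moderate->chd,0.009,fixed,,
disease_incidence,moderate->t2d,0.0038,fixed,,
disease_incidence,moderate->stroke,0.0033,fixed,,
disease_incidence,moderate->depression,0.0094,fixed,,
disease_incidence,recommended->colorectal_cancer,0.0096,fixed,,
disease_incidence,recommended->chd,0.008,fixed,,
disease_incidence,recommended->t2d,0.0033,fixed,,
disease_incidence,recommended->stroke,0.0029,fixed,,
disease_incidence,recommended->depression,0.0092,fixed,,
mortality,inactive->dead,0.016,fixed,,
mortality,moderate->dead,0.012,fixed,,
mortality,recommended->dead,0.01,fixed,,
mortality,colorectal_cancer->dead,0.092,fixed,,
mortality,chd->dead,0.002,fixed,,
mortality,t2d->dead,0.015,fixed,,
mortality,stroke->dead,0.4,fixed,,
mortality,depression->dead,0.03,fixed,,
utilities.trial,inactive,0.909,beta,3.0,0.38
utilities.trial,moderate,0.919,beta,5.1,0.51
utilities.trial,recommended,0.922,beta,5.1,0.43
utilities.literature,inactive,0.8,fixed,,
utilities.literature,moderate,0.87,fixed,,
utilities.literature,recommended,0.91,fixed,,
utilities.disease,colorectal_cancer,0.786,fixed,,
utilities.disease,chd,0.735,fixed,,
utilities.disease,t2d,0.785,fixed,,
utilities.disease,stroke,0.62,fixed,,
utilities.disease,depression,0.57,fixed,,
costs.societal,inactive,2436.0,gamma,0.19,12658.0
costs.societal,moderate,1506.0,gamma,0.22,6920.0
costs.societal,recommended,1997.0,gamma,0.24,8222.0
costs.societal,colorectal_cancer,34085.0,fixed,,
costs.societal,chd,5239.0,fixed,,
costs.societal,t2d,5907.0,fixed,,
costs.societal,stroke,24979.0,fixed,,
costs.societal,depression,6819.0,fixed,,
costs.healthcare,inactive,1107.0,gamma,0.1,10924.0
costs.healthcare,moderate,594.0,gamma,0.35,1707.0
costs.healthcare,recommended,747.0,gamma,0.19,4040.0
costs.healthcare,colorectal_cancer,25346.0,fixed,,
costs.healthcare,chd,1954.0,fixed,,
costs.healthcare,t2d,3089.0,fixed,,
costs.healthcare,stroke,18750.0,fixed,,
costs.healthcare,depression,966.0,fixed,,
costs,program,260.0,fixed,,
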