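raw,snomed_code,display,editions
ABDOMEN,818981001,Abdomen,
ANKLE,344001,Ankle region structure,
AORTA,15825003,Aortic structure,
ARM,53120007,Upper limb structure,
BLADDER,89837001,Urinary bladder structure,
BRAIN,12738006,Brain structure,
BREAST,76752008,Breast structure,
CHEST,51185008,Thoracic structure,
CLAVICLE,51299004,Clavicle structure,
COLON,71854001,Colon structure,
CSPINE,122494005,Cervical spine structure,
ELBOW,127949000,Elbow joint structure,
ESOPHAGUS,32849002,Esophageal structure,
EXTREMITY,66019005,Limb structure,
FACE,89545001,Face structure,
FEMUR,71341001,Femur structure,
FINGER,7569003,Finger structure,
FOOT,56459004,Foot structure,
HAND,85562004,Hand structure,
HEAD,69536005,Head structure,
HEART,80891009,Heart structure,
HIP,29836001,Hip region structure,
JAW,661005,Jaw region structure,
KIDNEY,64033007,Kidney structure,
KNEE,72696002,Knee region structure,
LEG,30021000,Lower leg structure,-2022d
LIVER,10200004,Liver structure,
LOWERLEG,30021000,Lower leg structure,2023a-
LSPINE,122496007,Lumbar spine structure,
LUNG,39607008,Lung structure,
MANDIBLE,91609006,Mandible structure,
MAXILLA,70925003,Maxilla structure,
NECK,45048000,Neck structure,
NOSE,45206002,Nasal structure,
ORBIT,363654007,Orbital structure,
PANCREAS,15776009,Pancreatic structure,
PELVIS,12921003,Pelvic structure,
PROSTATE,41216001,Prostate structure,
RECTUM,34402009,Rectum structure,
SHOULDER,16982005,Shoulder region structure,
SKULL,89546000,Skull structure,
SPINE,421060004,Vertebral column structure,
SPLEEN,78961009,Spleen structure,
STOMACH,69695003,Stomach structure,
THIGH,68367000,Thigh structure,
THYROID,69748006,Thyroid structure,
TOE,29707007,Toe structure,
TSPINE,122495006,Thoracic spine structure,
UTERUS,35039007,Uterine structure,
WHOLEBODY,38266002,Entire body,
WRIST,8205005,Wrist region structure,
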